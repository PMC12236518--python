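# Packaged fixture parameters for the synthetic generators.
# Temperatures in degC, concentrations in uM, times in s, wavenumbers in cm-1.

dsf_common: &dsf_common
  transition_slope: 1.5
  f_pre: 1000.0
  f_post: 10000.0
  decay_onset: 80.0
  decay_rate: 0.08
  noise_sd: 90.0        # 1% of the 9000 a.u. transition amplitude
  n_replicates: 2
  temp_grid: {start: 25.0, stop: 95.0, step: 0.25}

dsf:
  control:
    <<: *dsf_common
    tm_true: 53.4
  KG-96:
    <<: *dsf_common
    tm_true: 57.2
  KG-408:
    <<: *dsf_common
    tm_true: 57.3
  KG-484:
    <<: *dsf_common
    tm_true: 63.4

std_common: &std_common
  protein_conc: 20.0
  ligand_concs: [200.0, 400.0, 600.0, 800.0, 1000.0]
  sat_times: [0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0]
  # aromatic ligand regions receiving saturation transfer
  epitopes:
    "8.39-8.42ppm": {alpha_std: 3.0, ksat_ref: 0.8}
    "7.78-7.83ppm": {alpha_std: 4.5, ksat_ref: 0.6}
    "7.26-7.42ppm": {alpha_std: 2.0, ksat_ref: 1.0}
  noise_cv: 0.03

std:
  KG-96:
    <<: *std_common
    kd_true: 171.0
  KG-408:
    <<: *std_common
    kd_true: 376.0
  KG-484:
    <<: *std_common
    kd_true: 841.0

screen:
  n_compounds: 760
  control_tm: 53.4
  library_delta_sd: 2.3
  hit_fraction: 0.04
  hit_delta_range: [3.0, 10.0]
  n_control_wells: 8
  biphasic_fraction: 0.0

ir_common: &ir_common
  wavenumber_grid: {start: 1588.0, stop: 1712.0, step: 1.0}
  temp_grid: {start: 25.0, stop: 75.0, step: 1.0}
  noise_sd: 0.008       # ~0.5% of the composite peak absorbance

ir:
  apo:
    <<: *ir_common
    bands:
      - {center: 1605.0, width: 6.0, base_amplitude: 0.15, structure_class: side_chain,    melt_tm: 50.0, melt_slope: 2.5, post_melt_fraction: 0.6}
      - {center: 1633.0, width: 6.0, base_amplitude: 0.70, structure_class: native_beta,   melt_tm: 48.0, melt_slope: 2.0, post_melt_fraction: 0.15}
      - {center: 1640.0, width: 6.0, base_amplitude: 0.50, structure_class: native_beta,   melt_tm: 48.0, melt_slope: 2.0, post_melt_fraction: 0.15}
      - {center: 1645.0, width: 6.0, base_amplitude: 0.45, structure_class: unordered,     melt_tm: 48.0, melt_slope: 3.0, post_melt_fraction: 1.8}
      - {center: 1651.0, width: 6.0, base_amplitude: 0.80, structure_class: alpha_helix_cc, melt_tm: 50.0, melt_slope: 2.0, post_melt_fraction: 0.35}
      - {center: 1656.0, width: 6.0, base_amplitude: 1.00, structure_class: alpha_helix,   melt_tm: 50.0, melt_slope: 2.0, post_melt_fraction: 0.30}
      - {center: 1667.0, width: 6.0, base_amplitude: 0.40, structure_class: turn,          melt_tm: 49.0, melt_slope: 2.5, post_melt_fraction: 0.50}
      - {center: 1678.0, width: 6.0, base_amplitude: 0.30, structure_class: turn,          melt_tm: 49.0, melt_slope: 2.5, post_melt_fraction: 0.50}
    aggregate_band: {center: 1619.0, width: 6.0, amplitude: 0.90, growth_tm: 50.0, growth_slope: 2.0}
  KG-408:
    # ligand-bound ramp: native beta-sheet midpoint shifted +14 degC,
    # helix classes +4.5/+5, turns and unordered +5, aggregation delayed
    <<: *ir_common
    bands:
      - {center: 1605.0, width: 6.0, base_amplitude: 0.15, structure_class: side_chain,    melt_tm: 54.0, melt_slope: 2.5, post_melt_fraction: 0.6}
      - {center: 1633.0, width: 6.0, base_amplitude: 0.70, structure_class: native_beta,   melt_tm: 62.0, melt_slope: 2.0, post_melt_fraction: 0.15}
      - {center: 1640.0, width: 6.0, base_amplitude: 0.50, structure_class: native_beta,   melt_tm: 62.0, melt_slope: 2.0, post_melt_fraction: 0.15}
      - {center: 1645.0, width: 6.0, base_amplitude: 0.45, structure_class: unordered,     melt_tm: 53.0, melt_slope: 3.0, post_melt_fraction: 1.8}
      - {center: 1651.0, width: 6.0, base_amplitude: 0.80, structure_class: alpha_helix_cc, melt_tm: 54.5, melt_slope: 2.0, post_melt_fraction: 0.35}
      - {center: 1656.0, width: 6.0, base_amplitude: 1.00, structure_class: alpha_helix,   melt_tm: 55.0, melt_slope: 2.0, post_melt_fraction: 0.30}
      - {center: 1667.0, width: 6.0, base_amplitude: 0.40, structure_class: turn,          melt_tm: 54.0, melt_slope: 2.5, post_melt_fraction: 0.50}
      - {center: 1678.0, width: 6.0, base_amplitude: 0.30, structure_class: turn,          melt_tm: 54.0, melt_slope: 2.5, post_melt_fraction: 0.50}
    aggregate_band: {center: 1619.0, width: 6.0, amplitude: 0.90, growth_tm: 62.0, growth_slope: 2.0}
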