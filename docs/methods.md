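# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## DSF melt-curve analysis

**Model.** Protein unfolding exposes hydrophobic surface to a
reporter dye, so fluorescence rises sigmoidally with temperature and
then decays as the dye dissociates from the aggregating unfolded
state.  The rising limb (trace start to the global fluorescence
maximum) is fit by least squares to the two-state Boltzmann sigmoid
`F(T) = f_pre + (f_post − f_pre)/(1 + exp((Tm − T)/slope))`; the model
is invalid past the peak, which is why the window stops there.  `tm_se`
comes from the fit covariance; non-convergence falls back to the
smoothed-derivative maximum with a `poor_fit` flag.

**QC.** A well is `low_amplitude` when its total signal range is below
5% of its signal level (no transition to fit).  A well is `biphasic`
when the 5-point-smoothed first derivative of the rising limb has two
or more local maxima, each with height and prominence above 20% of the
largest; peaks narrower than 2 °C at half prominence are ignored
because a genuine two-state transition's derivative peak spans several
degrees (≈3.5 × slope) while noise bumps do not.  A fit with r² below
0.9 is `poor_fit`.

**Hit calling.** The threshold is the control mean Tm plus **one
standard deviation of the compound mean-Tm distribution** across the
usable (non-discarded) screen, and a hit must exceed it strictly.  The
control's replicate SD is far too small (hundredths of a degree) to
define a meaningful screen threshold; the spread of the compound
population is the natural yardstick for "unusually stabilized".
Compounds are discarded before thresholding when any replicate is
biphasic or poorly fit, or when replicates disagree by more than the
reproducibility tolerance (default 2 °C).

## STD NMR affinity estimation

For each ligand spectral region ("epitope") the amplification factor
`STD-AF = ε · I_diff/I_ref` with `ε = [L]_total/[P]_total` is computed
per saturation time and concentration.  Each (epitope, concentration)
series is fit to the exponential buildup
`AF(t) = AF_max(1 − e^{−k_sat t})`; the initial slope
`AF_0 = AF_max · k_sat` cancels the rebinding/relaxation bias that
makes long-saturation plateaus concentration-unreliable.  Its standard
error is first-order (delta-method) propagation from the
(AF_max, k_sat) covariance.  `AF_0` versus total ligand concentration
is then fit to the Langmuir isotherm
`AF_0([L]) = α_STD·[L]/([L]+K_d)` by weighted least squares (weights
1/SE², treated as absolute errors so the parameter covariance is not
rescaled by residual χ²; unweighted when SEs are absent), with K_d
bounded in (0, 100 × max [L]] and initialized at α = max AF_0,
K_d = median concentration.  Per-epitope K_d values are combined by
inverse-variance weighting, the standard meta-analytic estimator; a
fit without a finite SE is excluded, and when none has one an
unweighted mean is returned with a warning.

Assumptions worth keeping in mind: free ligand ≈ total ligand
(valid at [L] ≫ [P], as in the 200–1000 µM versus 20 µM design); fast
exchange; k_sat constant across concentrations within an epitope (the
standard initial-slope simplification); the reference integral is a
per-record quantity.  The protein concentration is a **required
input** everywhere — experiments are run at different [P] and a silent
default would corrupt ε.

Region integrals are trapezoidal integrals of the *absolute*
intensity over the ppm window, with the window boundaries included by
linear interpolation; ascending or descending ppm axes are accepted.

## MMS amide-I thermal-ramp analysis

**Processing chain.** Differential absorbance is rescaled to the
absolute scale by the instrument's nominal displacement factor
(default 0.63 — a scalar gain; all fractional outputs are invariant to
it).  The similarity spectrum is the Savitzky–Golay second derivative
(window 19 points, polynomial order 3 — order 3 is the lowest that
gives an unbiased smoothed second derivative), negated, baselined by
the straight line through the two end-region minima, and floored at
zero.

**Band unmixing.** The band model assigns Gaussian sub-bands to
structure classes: aggregated (intermolecular) β-sheet 1619/1691 cm⁻¹,
native β-sheet 1633/1640, unordered 1645, coiled-coil helix 1651,
canonical helix 1656, turns 1667/1678, and a Tyr side-chain band at
1605 cm⁻¹; default width 6 cm⁻¹ (bounds 3–12), centers movable by
±2 cm⁻¹ when refinement is on, all overridable via YAML.  Flooring the
similarity spectrum at zero is irreversible — exactly the shoulder
regions where neighbouring bands overlap are zeroed — so the
`SimilaritySpectrum` retains the unclipped inverted derivative and the
deconvolution unmixes band amplitudes against each Gaussian's own
smoothed-second-derivative signature.  Differentiation is linear, so
in that space the mixture model is exact and the non-negative
least-squares problem is well conditioned; the active-set NNLS solver
is used (exact, and solved on a norm-normalized signal so fractions
are strictly scale-invariant).  A similarity spectrum constructed
directly from Gaussian bands (no stored derivative) is fit with the
Gaussians themselves.  Class fractions are per-class sums of band
areas `amplitude · width · √(2π)` over the total; the side-chain band
is excluded from the normalization by default because it is not
secondary structure.

**Melting temperatures.** Across a ramp the band shapes are locked
(no per-temperature center/width refinement) so traces reflect
amplitude changes only.  Per class, the default trace is the
**absolute class band area**, fit to a logistic sigmoid whose midpoint
is the class Tm; the fractional-contribution trace is available
(`signal="fraction"`) but couples classes through its normalization —
a class appears to melt when another grows — which biases shift
estimates by ~1 °C in realistic mixtures.  A derivative-maximum
estimate (`method="derivative"`) is provided alongside the sigmoid
midpoint; on clean data they agree to the grid step.  Classes whose
trace varies by less than 2% of its magnitude are flagged flat with
undefined Tm.  The global Tm is the logistic midpoint of
`1 − Pearson correlation` between each similarity spectrum and the
lowest-temperature one.  Tm versus ligand concentration is fit to a
rectangular hyperbola `Tm([L]) = Tm₀ + ΔTm_max·[L]/([L]+EC50)` (Hill
coefficient 1; no evidence of cooperativity); when ΔTm_max is
indistinguishable from zero the EC50 is flagged unidentifiable.

## Synthetic generators

The generators are phenomenological at exactly the level the fits
assume; they do not simulate dye photophysics, NOE transfer, spin
relaxation or IR optics.

* **DSF**: Boltzmann sigmoid times an exponential dye-dissociation
  decay beyond a fixed onset (80 °C), additive Gaussian noise.
  Defaults: 25–95 °C at 0.25 °C, amplitude 9000 a.u. over a 1000 a.u.
  baseline, noise 1% of amplitude, duplicate wells.
* **Screen**: `library_delta_sd` (2.3 °C in the fixture) is the
  *marginal* SD of the full compound-Tm distribution; the non-hit
  jitter SD is derived from the hit fraction (4%) and hit-delta range
  (3–10 °C) so the realized spread matches and the analytic hit
  threshold is exactly `control_tm + library_delta_sd`.  Truth labels
  use the same one-SD rule applied to the true Tm values, with planted
  compounds recorded separately.
* **STD**: generated exactly from the buildup/Langmuir relations with
  `AF_max·k_sat = α_STD[L]/([L]+K_d)`; multiplicative lognormal noise
  (CV default 3%) on difference integrals only, since integrals are
  positive with signal-proportional errors and reference spectra are
  high-SNR.  The fixture design is 3 epitopes × 5 concentrations
  (200–1000 µM) × 8 saturation times (0.5–5 s) at 20 µM protein.
* **Amide-I**: Gaussian band sums whose native-band amplitudes follow
  falling sigmoids (a post-melt fraction > 1 models unordered gain)
  and whose aggregate band rises sigmoidally; total area is *not*
  conserved.  Grid 1588–1712 cm⁻¹ at 1 cm⁻¹, ramp 25–75 °C at 1 °C,
  additive noise 0.5% of the composite peak.

No assay's noise magnitude is prescribed by the experimental design
itself; the defaults above (DSF 1% of amplitude, STD CV 3%, IR 0.5% of
peak) are package choices representative of well-behaved instruments.
Because the generators share the fits' functional forms, passing
recovery tests demonstrates correctness of the estimators and their
error propagation — not robustness to model misspecification (baseline
drift, non-two-state unfolding, exchange-regime changes, water-vapor
residuals) that real data can show.

## Reproducibility and problem sizes

Every generator takes an explicit integer seed and is bit-for-bit
reproducible; the end-to-end runner derives all stage seeds from the
single config seed and stamps every artifact with the config hash.
Default analysis sizes — a 760-compound duplicate screen, 120-record
STD designs, 51-temperature ramps, and 50-replicate recovery studies
in the tests — run in seconds to a couple of minutes on one CPU; the
demo runner uses a 120-compound screen for brevity.

## Known limitations

* The DSF stage extracts no thermodynamic parameters (ΔH, ΔG) and does
  no plate-layout normalization beyond the control wells.
* Solubility-based discards in a real screen have no data-side
  analogue; only fit-quality proxies are implemented.
* The STD stage has no T₁-bias correction, epitope mapping, or
  slow/intermediate-exchange models.
* The MMS stage assumes inputs are already differential-absorbance
  corrected (dark scans, water vapor, phase alignment are
  instrument-side), and the displacement-factor normalization is
  modeled as a scalar.
* Gaussian band centers for the amide-I model are literature-informed
  defaults and should be overridden per protein where better
  assignments exist.
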