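"""Synthetic datasets with known ground truth for all three assay stages.

The generators are phenomenological at exactly the level the fits
assume (no dye photophysics, NOE transfer or IR optics):

* DSF traces are two-state Boltzmann sigmoids with an exponential
  dye-dissociation decay past a fixed onset temperature and additive
  Gaussian noise.
* STD datasets obey the amplification-factor buildup and Langmuir
  relations generatively — AF_max·k_sat = alpha_STD·[L]/([L]+K_d) — with
  multiplicative lognormal noise on the difference integrals (integrals
  are positive and their errors scale with signal).
* Amide-I series are Gaussian band sums whose native-band amplitudes
  follow falling sigmoids and whose aggregated-β band grows with a
  rising sigmoid; total band area is not conserved.

Every generator is driven by an explicit integer seed and reproduces
its output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dsf import MeltCurve
from .stdnmr import STDDataset

__all__ = [
    "DSFGenParams",
    "ScreenSpec",
    "BindingTruth",
    "IRBandTruth",
    "AggregateBand",
    "IRGenParams",
    "generate_dsf_curve",
    "generate_screen",
    "generate_std_dataset",
    "generate_ir_series",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# DSF


@dataclass(frozen=True)
class DSFGenParams:
    """Ground truth for one melt-curve condition.

    ``biphasic``, when set, is a (tm2, slope2, amplitude_fraction)
    triple adding a second transition with the given amplitude relative
    to the main one.
    """

    tm_true: float = 53.4
    transition_slope: float = 1.5
    f_pre: float = 1000.0
    f_post: float = 10000.0
    decay_onset: float = 80.0
    decay_rate: float = 0.08
    noise_sd: float = 90.0
    n_replicates: int = 2
    temp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(25.0, 95.0 + 1e-9, 0.25))
    biphasic: tuple[float, float, float] | None = None

    def validate(self) -> None:
        t = np.asarray(self.temp_grid, dtype=float)
        if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("temp_grid must be 1-D and strictly increasing")
        if self.f_post < self.f_pre:
            raise ValueError("f_post must be >= f_pre")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (t[0] <= self.tm_true <= t[-1]):
            raise ValueError("tm_true must lie within the temperature grid")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def noiseless_dsf_trace(params: DSFGenParams) -> np.ndarray:
    """Rise-then-fall fluorescence trace without noise."""
    t = np.asarray(params.temp_grid, dtype=float)
    shape = _sigmoid((t - params.tm_true) / params.transition_slope)
    if params.biphasic is not None:
        tm2, slope2, amp2 = params.biphasic
        shape = (shape + amp2 * _sigmoid((t - tm2) / slope2)) / (1.0 + amp2)
    decay = np.exp(-params.decay_rate * np.clip(t - params.decay_onset, 0.0, None))
    return params.f_pre + (params.f_post - params.f_pre) * shape * decay


def generate_dsf_curve(params: DSFGenParams, seed: int,
                       compound_id: str = "compound",
                       well_prefix: str = "W") -> list[MeltCurve]:
    """Generate ``n_replicates`` noisy melt curves for one condition."""
    params.validate()
    rng = np.random.default_rng(seed)
    return _gen_curves(params, rng, compound_id, well_prefix)


def _gen_curves(params: DSFGenParams, rng: np.random.Generator,
                compound_id: str, well_prefix: str) -> list[MeltCurve]:
    base = noiseless_dsf_trace(params)
    curves = []
    for i in range(params.n_replicates):
        noise = rng.normal(0.0, params.noise_sd, size=base.size) if params.noise_sd > 0 \
            else np.zeros_like(base)
        curves.append(MeltCurve(
            well_id=f"{well_prefix}{i + 1}",
            compound_id=compound_id,
            temperature=np.asarray(params.temp_grid, dtype=float).copy(),
            fluorescence=base + noise,
            replicate_index=i,
        ))
    return curves


@dataclass(frozen=True)
class ScreenSpec:
    """Design of a synthetic fragment screen.

    ``library_delta_sd`` is the marginal standard deviation of the full
    compound-Tm distribution (planted hits included); the non-hit
    jitter SD is derived from it so the realized spread matches, making
    the analytic hit threshold ``control_tm + library_delta_sd``.
    """

    n_compounds: int = 760
    control_tm: float = 53.4
    library_delta_sd: float = 2.3
    hit_fraction: float = 0.04
    hit_delta_range: tuple[float, float] = (3.0, 10.0)
    seed: int = 0
    n_control_wells: int = 8
    biphasic_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.library_delta_sd < 0:
            raise ValueError("library_delta_sd must be non-negative")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError("hit_fraction must lie in [0, 1]")
        if not 0.0 <= self.biphasic_fraction <= 1.0:
            raise ValueError("biphasic_fraction must lie in [0, 1]")
        a, b = self.hit_delta_range
        if not a <= b:
            raise ValueError("hit_delta_range must be ordered")

    def nonhit_sd(self) -> float:
        """Non-hit jitter SD giving a marginal compound-Tm SD of library_delta_sd."""
        n_hits = round(self.hit_fraction * self.n_compounds)
        f = n_hits / self.n_compounds
        if f == 0:
            return self.library_delta_sd
        a, b = self.hit_delta_range
        m1 = 0.5 * (a + b)
        m2 = (a * a + a * b + b * b) / 3.0
        var0 = (self.library_delta_sd**2 - f * m2 + (f * m1) ** 2) / (1.0 - f)
        if var0 < 0:
            raise ValueError(
                "library_delta_sd too small for the requested hit fraction and delta range")
        return float(np.sqrt(var0))


def generate_screen(spec: ScreenSpec,
                    base_params: DSFGenParams | None = None,
                    control_id: str = "DMSO",
                    ) -> tuple[list[MeltCurve], pd.DataFrame]:
    """Generate a duplicate-well fragment screen plus its truth table.

    Returns the melt curves (two replicate wells per compound plus
    ``n_control_wells`` control wells) and a truth table with each
    compound's true Tm, whether it was planted as a stabilizer, and its
    hit label under the one-SD threshold rule (true Tm strictly above
    control Tm + SD of the true compound-Tm distribution; compounds
    planted with biphasic curves are never hits and are excluded from
    the SD).
    """
    spec.validate()
    base = base_params or DSFGenParams(tm_true=spec.control_tm, noise_sd=0.0)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_hits = round(spec.hit_fraction * n)
    hit_idx = np.zeros(n, dtype=bool)
    if n_hits:
        hit_idx[rng.choice(n, size=n_hits, replace=False)] = True
    deltas = np.where(
        hit_idx,
        rng.uniform(spec.hit_delta_range[0], spec.hit_delta_range[1], size=n),
        rng.normal(0.0, spec.nonhit_sd(), size=n),
    )
    true_tm = spec.control_tm + deltas

    biphasic_idx = np.zeros(n, dtype=bool)
    n_biph = round(spec.biphasic_fraction * n)
    if n_biph:
        candidates = np.flatnonzero(~hit_idx)
        biphasic_idx[rng.choice(candidates, size=min(n_biph, candidates.size),
                                replace=False)] = True

    usable = ~biphasic_idx
    sd_true = float(np.std(true_tm[usable], ddof=1)) if usable.sum() > 1 else 0.0
    threshold = spec.control_tm + sd_true
    hit_label = (true_tm > threshold) & usable

    curves: list[MeltCurve] = []
    for i in range(n):
        cid = f"C{i + 1:04d}"
        p = replace(base, tm_true=float(true_tm[i]), n_replicates=2)
        if biphasic_idx[i]:
            p = replace(p, biphasic=(float(true_tm[i] + 8.0), base.transition_slope, 1.0))
        curves.extend(_gen_curves(p, rng, cid, well_prefix=f"{cid}-"))
    ctrl = replace(base, tm_true=spec.control_tm, n_replicates=spec.n_control_wells,
                   biphasic=None)
    curves.extend(_gen_curves(ctrl, rng, control_id, well_prefix="CTRL-"))

    truth = pd.DataFrame({
        "compound": [f"C{i + 1:04d}" for i in range(n)],
        "true_tm": true_tm,
        "true_delta": deltas,
        "planted": hit_idx,
        "biphasic": biphasic_idx,
        "hit": hit_label,
    })
    truth.attrs["threshold"] = threshold
    truth.attrs["control_tm"] = spec.control_tm
    return curves, truth


# ---------------------------------------------------------------------------
# STD NMR


@dataclass(frozen=True)
class BindingTruth:
    """Ground-truth binding parameters for one ligand.

    ``alpha_std`` and ``ksat_ref`` are per-epitope (keyed by region
    label); ``ksat_ref`` is held constant across concentrations for
    each epitope (standard initial-slope simplification).
    Concentrations in µM, times in s.
    """

    kd_true: float
    alpha_std: dict[str, float]
    ksat_ref: dict[str, float]
    protein_conc: float = 20.0
    ligand_concs: tuple[float, ...] = (200.0, 400.0, 600.0, 800.0, 1000.0)
    sat_times: tuple[float, ...] = (0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0)

    def validate(self) -> None:
        if self.kd_true <= 0 or self.protein_conc <= 0:
            raise ValueError("kd_true and protein_conc must be positive")
        if not self.ligand_concs or not self.sat_times:
            raise ValueError("ligand_concs and sat_times must be non-empty")
        if any(c <= 0 for c in self.ligand_concs) or any(t <= 0 for t in self.sat_times):
            raise ValueError("concentrations and saturation times must be positive")
        if set(self.alpha_std) != set(self.ksat_ref):
            raise ValueError("alpha_std and ksat_ref must cover the same epitopes")


def std_af_true(truth: BindingTruth, epitope: str, ligand_conc: float,
                sat_time: float) -> float:
    """Noiseless STD amplification factor for one condition."""
    af0 = truth.alpha_std[epitope] * ligand_conc / (ligand_conc + truth.kd_true)
    k = truth.ksat_ref[epitope]
    af_max = af0 / k
    return af_max * (1.0 - np.exp(-k * sat_time))


def generate_std_dataset(truth: BindingTruth, noise_cv: float, seed: int,
                         i_ref_scale: float = 1000.0) -> STDDataset:
    """Generate an STD integral table obeying the buildup/Langmuir relations.

    For each (epitope, [L], t_sat) the noiseless amplification factor
    is AF_max·(1−exp(−k_sat·t_sat)) with AF_max·k_sat =
    alpha_STD·[L]/([L]+K_d).  Difference integrals are derived through
    epsilon = [L]/[P] against a constant reference integral and carry
    multiplicative lognormal noise with coefficient of variation
    ``noise_cv``; reference integrals are noiseless (high-SNR spectra).
    """
    truth.validate()
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    rows = []
    for epitope in truth.alpha_std:
        for conc in truth.ligand_concs:
            eps = conc / truth.protein_conc
            for t in truth.sat_times:
                af = std_af_true(truth, epitope, conc, t)
                i_diff = (af / eps) * i_ref_scale
                if noise_cv > 0:
                    i_diff *= rng.lognormal(-0.5 * sigma**2, sigma)
                rows.append((epitope, conc, t, i_diff, i_ref_scale))
    records = pd.DataFrame(rows, columns=["epitope", "ligand_conc_uM", "sat_time_s",
                                          "i_diff", "i_ref"])
    return STDDataset(records, truth.protein_conc)


# ---------------------------------------------------------------------------
# Amide-I IR


@dataclass(frozen=True)
class IRBandTruth:
    """One native amide-I band and its thermal behaviour.

    Amplitude follows a falling sigmoid from ``base_amplitude`` to
    ``base_amplitude * post_melt_fraction`` with midpoint ``melt_tm``;
    a ``post_melt_fraction`` above 1 models a band that grows on
    unfolding (e.g. unordered structure).
    """

    center: float
    width: float
    base_amplitude: float
    structure_class: str
    melt_tm: float
    melt_slope: float
    post_melt_fraction: float

    def validate(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0 or self.post_melt_fraction < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class AggregateBand:
    """Aggregated (intermolecular) β-sheet band growing with a rising sigmoid."""

    center: float
    width: float
    amplitude: float
    growth_tm: float
    growth_slope: float

    def validate(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class IRGenParams:
    """Ground truth for a thermal-ramp amide-I series."""

    band_truth: tuple[IRBandTruth, ...]
    aggregate_band: AggregateBand
    wavenumber_grid: np.ndarray = field(
        default_factory=lambda: np.arange(1588.0, 1712.0 + 1e-9, 1.0))
    temp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(25.0, 75.0 + 1e-9, 1.0))
    noise_sd: float = 0.008

    def validate(self) -> None:
        if not self.band_truth:
            raise ValueError("at least one band required")
        for b in self.band_truth:
            b.validate()
        self.aggregate_band.validate()
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for grid in (self.wavenumber_grid, self.temp_grid):
            g = np.asarray(grid, dtype=float)
            if g.ndim != 1 or not np.all(np.diff(g) > 0):
                raise ValueError("grids must be 1-D and strictly increasing")


def band_amplitude(band: IRBandTruth, temperature: np.ndarray) -> np.ndarray:
    """Sigmoidal amplitude of a native band along the temperature ramp."""
    t = np.asarray(temperature, dtype=float)
    frac_folded = 1.0 - _sigmoid((t - band.melt_tm) / band.melt_slope)
    return band.base_amplitude * (
        band.post_melt_fraction + (1.0 - band.post_melt_fraction) * frac_folded)


def noiseless_ir_spectrum(params: IRGenParams, temperature: float) -> np.ndarray:
    """One temperature's spectrum as the analytic Gaussian band sum."""
    wn = np.asarray(params.wavenumber_grid, dtype=float)
    spec = np.zeros_like(wn)
    for b in params.band_truth:
        amp = float(band_amplitude(b, np.array([temperature]))[0])
        spec += amp * np.exp(-0.5 * ((wn - b.center) / b.width) ** 2)
    agg = params.aggregate_band
    amp = agg.amplitude * float(_sigmoid((temperature - agg.growth_tm) / agg.growth_slope))
    spec += amp * np.exp(-0.5 * ((wn - agg.center) / agg.width) ** 2)
    return spec


def generate_ir_series(params: IRGenParams, seed: int, meta: dict | None = None):
    """Generate a differential-absorbance thermal-ramp series with noise."""
    from .mms import IRSpectrumSeries

    params.validate()
    rng = np.random.default_rng(seed)
    temps = np.asarray(params.temp_grid, dtype=float)
    spectra = np.stack([noiseless_ir_spectrum(params, float(t)) for t in temps])
    if params.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, params.noise_sd, size=spectra.shape)
    return IRSpectrumSeries(
        wavenumbers=np.asarray(params.wavenumber_grid, dtype=float).copy(),
        temperatures=temps.copy(),
        absorbance=spectra,
        meta=dict(meta or {}),
    )
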