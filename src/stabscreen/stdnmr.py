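"""Saturation transfer difference (STD) NMR binding analysis.

Saturation applied to protein resonances is transferred to the protons
of a transiently bound ligand via intermolecular NOE, so the difference
between on- and off-resonance spectra reports direct binding.  The STD
amplification factor for a ligand spectral region ("epitope") is

    STD-AF = epsilon * I_diff / I_ref,     epsilon = [L]_total / [P]_total

which grows with saturation time as a single-exponential buildup

    STD-AF(t) = AF_max * (1 - exp(-k_sat * t))

whose initial slope AF_0 = AF_max * k_sat removes rebinding/relaxation
bias.  AF_0 versus total ligand concentration follows a Langmuir
isotherm

    AF_0([L]) = alpha_STD * [L] / ([L] + K_d)

from which the dissociation constant K_d is estimated per epitope and
combined across epitopes by inverse-variance weighting.

Concentrations are in µM, saturation times in s throughout.  The
free-ligand ~ total-ligand approximation is used, valid when
[L] >> [P].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "EpitopeRegion",
    "STDDataset",
    "BuildupFit",
    "LangmuirFit",
    "KdEstimate",
    "integrate_region",
    "compute_std_af",
    "fit_buildup",
    "fit_langmuir",
    "combine_kd",
    "run_std_pipeline",
]

#: columns of the STD integral record table
RECORD_COLUMNS = ("epitope", "ligand_conc_uM", "sat_time_s", "i_diff", "i_ref")


@dataclass(frozen=True)
class EpitopeRegion:
    """A ligand spectral window (ppm) receiving saturation transfer."""

    label: str
    ppm_lo: float
    ppm_hi: float

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError("ppm_lo must be < ppm_hi")


@dataclass
class STDDataset:
    """Region integrals indexed by (epitope, ligand concentration, saturation time)."""

    records: pd.DataFrame
    protein_conc: float

    def __post_init__(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive (µM)")
        r = self.records
        if (r["i_ref"] <= 0).any():
            raise ValueError("reference integrals must be positive")
        if (r["sat_time_s"] <= 0).any() or (r["ligand_conc_uM"] <= 0).any():
            raise ValueError("saturation times and ligand concentrations must be positive")

    @property
    def epitopes(self) -> list[str]:
        return list(pd.unique(self.records["epitope"]))


@dataclass
class BuildupFit:
    """Exponential buildup parameters for one (epitope, concentration)."""

    af_max: float
    k_sat: float
    af0: float
    covariance: np.ndarray
    af0_se: float


@dataclass
class LangmuirFit:
    """Langmuir isotherm fit of AF_0 versus ligand concentration for one epitope."""

    alpha_std: float
    kd: float
    kd_se: float
    residual_rms: float
    epitope: str = ""
    flags: set = field(default_factory=set)


@dataclass
class KdEstimate:
    """Combined dissociation constant with per-epitope provenance."""

    kd_combined: float
    kd_combined_se: float
    per_epitope: list[LangmuirFit]
    buildup_fits: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kd_combined_uM": self.kd_combined,
            "kd_combined_se_uM": self.kd_combined_se,
            "per_epitope": [
                {
                    "epitope": f.epitope,
                    "alpha_std": f.alpha_std,
                    "kd_uM": f.kd,
                    "kd_se_uM": f.kd_se,
                    "flags": sorted(f.flags),
                }
                for f in self.per_epitope
            ],
        }


def integrate_region(ppm: np.ndarray, intensity: np.ndarray, region: EpitopeRegion) -> float:
    """Absolute (magnitude) trapezoidal integral over a ppm window.

    The spectrum may be stored with ppm ascending or descending; the
    region boundaries are included by linear interpolation.
    """
    ppm = np.asarray(ppm, dtype=float)
    y = np.abs(np.asarray(intensity, dtype=float))
    order = np.argsort(ppm)
    ppm, y = ppm[order], y[order]
    if region.ppm_lo < ppm[0] or region.ppm_hi > ppm[-1]:
        raise ValueError("integration region lies outside the spectral width")
    grid = np.unique(np.concatenate([
        [region.ppm_lo, region.ppm_hi],
        ppm[(ppm > region.ppm_lo) & (ppm < region.ppm_hi)],
    ]))
    vals = np.interp(grid, ppm, y)
    return float(np.trapezoid(vals, grid))


def compute_std_af(i_diff: float, i_ref: float, ligand_conc: float, protein_conc: float) -> float:
    """STD amplification factor epsilon * I_diff / I_ref with epsilon = [L]/[P]."""
    if i_ref <= 0:
        raise ValueError("reference integral must be positive")
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    return (ligand_conc / protein_conc) * (i_diff / i_ref)


def _buildup(t: np.ndarray, af_max: float, k_sat: float) -> np.ndarray:
    return af_max * (1.0 - np.exp(-k_sat * t))


def fit_buildup(points: list[tuple[float, float]]) -> BuildupFit:
    """Least-squares fit of the exponential STD buildup curve.

    Parameters
    ----------
    points
        (saturation time s, STD-AF) pairs; at least 3 distinct times.

    Returns
    -------
    BuildupFit
        ``af0 = af_max * k_sat`` with a standard error propagated to
        first order from the (af_max, k_sat) covariance.
    """
    t = np.array([p[0] for p in points], dtype=float)
    af = np.array([p[1] for p in points], dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct saturation times")
    if np.allclose(af, 0.0):
        cov = np.full((2, 2), np.nan)
        return BuildupFit(0.0, np.nan, 0.0, cov, 0.0)
    # initial slope from the earliest two points; reject decreasing data
    order = np.argsort(t)
    t, af = t[order], af[order]
    slope0 = (af[1] - af[0]) / (t[1] - t[0]) if af[0] != 0 else af[1] / t[1]
    if np.max(af) > 0 and slope0 < 0 and af[0] > af[-1]:
        raise ValueError("STD-AF decreases with saturation time; not a buildup curve")
    p0 = (float(np.max(af)), max(1.0 / float(np.median(t)), 1e-3))
    try:
        popt, pcov = curve_fit(_buildup, t, af, p0=p0,
                               bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"buildup fit failed to converge: {err}") from err
    af_max, k_sat = float(popt[0]), float(popt[1])
    af0 = af_max * k_sat
    grad = np.array([k_sat, af_max])
    var = float(grad @ pcov @ grad)
    af0_se = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.nan
    return BuildupFit(af_max, k_sat, af0, pcov, af0_se)


def _langmuir(conc: np.ndarray, alpha: float, kd: float) -> np.ndarray:
    return alpha * conc / (conc + kd)


def fit_langmuir(points: list[tuple[float, float, float | None]], epitope: str = "") -> LangmuirFit:
    """Weighted least-squares fit of AF_0 versus ligand concentration.

    ``points`` are (concentration µM, af0, af0_se) triples; standard
    errors, when finite and positive, weight the fit by 1/se².  K_d is
    bounded in (0, 100 × max concentration]; the fit is initialized at
    alpha = max(af0), K_d = median concentration.
    """
    conc = np.array([p[0] for p in points], dtype=float)
    af0 = np.array([p[1] for p in points], dtype=float)
    se = np.array([np.nan if len(p) < 3 or p[2] is None else p[2] for p in points], dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct ligand concentrations")
    if np.max(conc) / np.min(conc) < 2.0:
        warnings.warn("ligand concentrations span less than 2-fold; K_d poorly constrained",
                      stacklevel=2)
    flags: set = set()
    sigma = None
    if np.all(np.isfinite(se)) and np.all(se > 0):
        sigma = se
    kd_hi = 100.0 * float(np.max(conc))
    p0 = (float(np.max(af0)), float(np.median(conc)))
    try:
        popt, pcov = curve_fit(_langmuir, conc, af0, p0=p0, sigma=sigma,
                               absolute_sigma=sigma is not None,
                               bounds=([0.0, 1e-9], [np.inf, kd_hi]), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Langmuir fit failed to converge: {err}") from err
    alpha, kd = float(popt[0]), float(popt[1])
    kd_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    resid = af0 - _langmuir(conc, alpha, kd)
    # a plateau (saturated regime) drives K_d to its lower bound
    if np.ptp(af0) < 1e-12 * max(np.max(np.abs(af0)), 1.0) or kd < 1e-6 * np.min(conc):
        flags.add("saturated")
    return LangmuirFit(alpha, kd, kd_se, float(np.sqrt(np.mean(resid**2))), epitope, flags)


def combine_kd(fits: list[LangmuirFit]) -> KdEstimate:
    """Inverse-variance weighted mean of per-epitope K_d estimates.

    Fits without a finite standard error are excluded from the weighted
    mean; when none carries a finite SE an unweighted mean is returned
    with a warning.
    """
    if not fits:
        raise ValueError("no Langmuir fits to combine")
    kd = np.array([f.kd for f in fits], dtype=float)
    se = np.array([f.kd_se for f in fits], dtype=float)
    good = np.isfinite(se) & (se > 0)
    if not good.any():
        warnings.warn("no finite K_d standard errors; returning unweighted mean", stacklevel=2)
        return KdEstimate(float(np.mean(kd)), np.nan, list(fits))
    w = 1.0 / se[good] ** 2
    kd_c = float(np.sum(w * kd[good]) / np.sum(w))
    kd_se_c = float(np.sqrt(1.0 / np.sum(w)))
    return KdEstimate(kd_c, kd_se_c, list(fits))


def run_std_pipeline(dataset: STDDataset) -> KdEstimate:
    """Full STD analysis: buildup fits per condition, Langmuir per epitope, combined K_d.

    Each (epitope, concentration) group must span at least 3 saturation
    times and each epitope at least 3 concentrations.  An epitope whose
    buildup fits all fail is dropped with a warning.
    """
    buildups: dict[tuple[str, float], BuildupFit] = {}
    langmuirs: list[LangmuirFit] = []
    for epitope, edf in dataset.records.groupby("epitope", sort=False):
        pts = []
        for conc, cdf in edf.groupby("ligand_conc_uM", sort=True):
            af = [
                (row.sat_time_s,
                 compute_std_af(row.i_diff, row.i_ref, row.ligand_conc_uM, dataset.protein_conc))
                for row in cdf.itertuples()
            ]
            try:
                bf = fit_buildup(af)
            except (RuntimeError, ValueError) as err:
                warnings.warn(f"buildup fit failed for {epitope!r} at {conc} µM: {err}",
                              stacklevel=2)
                continue
            buildups[(str(epitope), float(conc))] = bf
            pts.append((float(conc), bf.af0, bf.af0_se if bf.af0_se and bf.af0_se > 0 else None))
        if len(pts) < 3:
            warnings.warn(f"epitope {epitope!r} dropped: fewer than 3 usable concentrations",
                          stacklevel=2)
            continue
        ses = [p[2] for p in pts]
        if any(s is None for s in ses):
            pts = [(c, a, None) for c, a, _ in pts]
        langmuirs.append(fit_langmuir(pts, epitope=str(epitope)))
    if not langmuirs:
        raise RuntimeError("no epitope produced a usable Langmuir fit")
    est = combine_kd(langmuirs)
    est.buildup_fits = buildups
    return est
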