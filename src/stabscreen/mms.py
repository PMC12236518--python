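"""Amide-I infrared thermal-ramp analysis (microfluidic modulation spectroscopy).

Differential absorbance spectra across the amide-I band
(1588–1712 cm⁻¹) report protein secondary structure: sub-bands map to
β-sheet, α-helix, turn, unordered and aggregated-β classes.  The
processing chain is

1. scalar normalization of differential to absolute absorbance
   (nominal displacement factor, default 0.63);
2. conversion to a "similarity spectrum": Savitzky–Golay second
   derivative (window 19, order 3), negated, linearly baselined through
   the end-region minima and floored at zero;
3. non-negative Gaussian band deconvolution against a band model with
   structure-class labels, yielding fractional higher-order-structure
   (HOS) composition;
4. per-class melting temperatures from logistic fits of fractional
   contribution versus temperature (with a derivative-maximum
   fallback), a global Tm from a spectral-dissimilarity trace, and an
   EC50 of ligand-driven thermal stabilization from global Tm versus
   ligand concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares, nnls
from scipy.signal import savgol_filter

__all__ = [
    "IRSpectrumSeries",
    "SimilaritySpectrum",
    "Band",
    "BandModel",
    "HOSComposition",
    "ClassMelt",
    "ThermalAnalysis",
    "EC50Fit",
    "STRUCTURE_CLASSES",
    "default_band_model",
    "normalize_spectrum",
    "similarity_spectrum",
    "deconvolve_bands",
    "melt_analysis",
    "fit_ec50",
    "run_thermal_ramp",
]

STRUCTURE_CLASSES = (
    "intermolecular_beta",
    "native_beta",
    "alpha_helix_cc",
    "alpha_helix",
    "turn",
    "unordered",
    "side_chain",
)

DEFAULT_DISPLACEMENT_FACTOR = 0.63
SG_WINDOW = 19
SG_ORDER = 3


@dataclass
class IRSpectrumSeries:
    """Absorbance matrix (temperature × wavenumber) for one sample."""

    wavenumbers: np.ndarray
    temperatures: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        t = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (t.size, wn.size):
            raise ValueError("absorbance must be (n_temperatures, n_wavenumbers)")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        self.wavenumbers, self.temperatures, self.absorbance = wn, t, a


@dataclass
class SimilaritySpectrum:
    """Inverted, baselined, smoothed second derivative of an absolute spectrum.

    ``values`` is the presentation form (non-negative after baselining).
    ``deriv`` retains the unclipped inverted smoothed second derivative:
    flooring at zero is irreversible and discards the shoulder
    information needed to unmix overlapped bands, so band fitting uses
    ``deriv`` whenever it is available.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    deriv: np.ndarray | None = None
    sg_window: int = SG_WINDOW
    sg_order: int = SG_ORDER


@dataclass(frozen=True)
class Band:
    label: str
    structure_class: str
    center: float
    center_tol: float = 2.0
    width: float = 6.0
    width_bounds: tuple[float, float] = (3.0, 12.0)

    def __post_init__(self) -> None:
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ValueError(f"unknown structure class {self.structure_class!r}")
        if self.width <= 0:
            raise ValueError("band width must be positive")


@dataclass
class BandModel:
    """Gaussian band table: centers, widths and structure-class labels."""

    bands: list[Band]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band model must contain at least one band")


def default_band_model() -> BandModel:
    """Literature-informed amide-I band assignment for a mixed α/β protein.

    Aggregated (intermolecular) β-sheet at 1619/1691 cm⁻¹, native
    β-sheet 1633/1640, unordered 1645, coiled-coil helix 1651 (the
    1650–1652 cm⁻¹ region is diagnostic of coiled-coil packing),
    canonical helix 1656, turns 1667/1678 and a Tyr-dominated
    side-chain band at 1605 cm⁻¹.
    """
    spec = [
        ("sc1605", "side_chain", 1605.0),
        ("agg1619", "intermolecular_beta", 1619.0),
        ("beta1633", "native_beta", 1633.0),
        ("beta1640", "native_beta", 1640.0),
        ("rc1645", "unordered", 1645.0),
        ("cc1651", "alpha_helix_cc", 1651.0),
        ("helix1656", "alpha_helix", 1656.0),
        ("turn1667", "turn", 1667.0),
        ("turn1678", "turn", 1678.0),
        ("agg1691", "intermolecular_beta", 1691.0),
    ]
    return BandModel([Band(label, cls, c) for label, cls, c in spec])


@dataclass
class HOSComposition:
    """Fractional secondary-structure composition from one spectrum."""

    fractions: dict[str, float]
    band_table: pd.DataFrame

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and np.isfinite(total) and abs(total - 1.0) > 1e-6:
            raise ValueError("class fractions must sum to 1")


@dataclass
class ClassMelt:
    tm: float
    tm_se: float
    method: str
    flags: set = field(default_factory=set)


@dataclass
class ThermalAnalysis:
    per_class: dict[str, ClassMelt]
    global_tm: float
    global_tm_se: float

    def to_dict(self) -> dict:
        return {
            "global_tm_C": self.global_tm,
            "global_tm_se_C": self.global_tm_se,
            "per_class": {
                k: {"tm_C": v.tm, "tm_se_C": v.tm_se, "method": v.method,
                    "flags": sorted(v.flags)}
                for k, v in self.per_class.items()
            },
        }


@dataclass
class EC50Fit:
    tm0: float
    delta_tm_max: float
    ec50: float
    ec50_se: float
    flags: set = field(default_factory=set)


def normalize_spectrum(differential: np.ndarray,
                       displacement_factor: float = DEFAULT_DISPLACEMENT_FACTOR) -> np.ndarray:
    """Rescale differential absorbance to the absolute scale.

    The instrument's nominal displacement factor is a scalar gain;
    dividing by it recovers absolute absorbance.  Downstream fractional
    compositions are invariant to this factor.
    """
    if displacement_factor <= 0:
        raise ValueError("displacement factor must be positive")
    return np.asarray(differential, dtype=float) / displacement_factor


def similarity_spectrum(wavenumbers: np.ndarray, absolute: np.ndarray,
                        sg_window: int = SG_WINDOW, sg_order: int = SG_ORDER) -> SimilaritySpectrum:
    """Inverted, baselined second derivative with Savitzky–Golay smoothing.

    The second derivative is taken with a Savitzky–Golay derivative
    filter (window ``sg_window`` points, polynomial order
    ``sg_order``), negated so bands point up, baselined by the straight
    line through the minima of the two spectrum end regions, and floored
    at zero.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(absolute, dtype=float)
    if sg_window % 2 == 0:
        raise ValueError("Savitzky–Golay window must be odd")
    if sg_window > y.size:
        raise ValueError("Savitzky–Golay window exceeds spectrum length")
    delta = float(np.mean(np.diff(wn)))
    d2 = savgol_filter(y, sg_window, sg_order, deriv=2, delta=delta)
    s = -d2
    k = max(5, s.size // 20)
    i_lo = int(np.argmin(s[:k]))
    i_hi = int(np.argmin(s[-k:])) + (s.size - k)
    if i_hi == i_lo:
        baseline = np.full_like(s, s[i_lo])
    else:
        slope = (s[i_hi] - s[i_lo]) / (wn[i_hi] - wn[i_lo])
        baseline = s[i_lo] + slope * (wn - wn[i_lo])
    return SimilaritySpectrum(wn, np.clip(s - baseline, 0.0, None), deriv=s,
                              sg_window=sg_window, sg_order=sg_order)


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _design_matrix(wn: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * ((wn[:, None] - centers[None, :]) / widths[None, :]) ** 2)


def _deriv_design_matrix(wn: np.ndarray, centers: np.ndarray, widths: np.ndarray,
                         sg_window: int, sg_order: int) -> np.ndarray:
    """Smoothed-second-derivative signature of each unit Gaussian band."""
    delta = float(np.mean(np.diff(wn)))
    cols = [
        -savgol_filter(_gaussian(wn, c, w), sg_window, sg_order, deriv=2, delta=delta)
        for c, w in zip(centers, widths)
    ]
    return np.array(cols).T


def deconvolve_bands(sim: SimilaritySpectrum, model: BandModel,
                     refine: bool = True,
                     include_side_chain: bool = False) -> HOSComposition:
    """Fit the band model to a similarity spectrum and report class fractions.

    Band amplitudes (on the absolute-absorbance scale) are constrained
    non-negative.  When the similarity spectrum carries its unclipped
    inverted second derivative (``sim.deriv``, set by
    :func:`similarity_spectrum`), each band is represented by the same
    smoothed-second-derivative transform of a unit Gaussian and the
    fit is a linear unmixing in derivative space — differentiation is
    linear, so overlapped bands remain identifiable there, which the
    floored presentation spectrum does not allow.  For a spectrum
    without a stored derivative (e.g. constructed directly from
    Gaussian bands) the Gaussians themselves are fit to ``values``.

    When ``refine`` is true, band centers may move within
    ``center_tol`` and widths within their bounds via bounded nonlinear
    least squares seeded from the linear non-negative fit.  Class
    fractions are Gaussian band areas (amplitude × width × √(2π))
    summed per class and normalized; the side-chain class is excluded
    from the normalization unless ``include_side_chain`` is set (it is
    not secondary structure).
    """
    wn = sim.wavenumbers
    centers = np.array([b.center for b in model.bands])
    widths = np.array([b.width for b in model.bands])
    seen = set()
    for b in model.bands:
        key = (b.center, b.width)
        if key in seen:
            warnings.warn(f"duplicate band at {b.center} cm⁻¹; design is rank-deficient",
                          stacklevel=2)
        seen.add(key)

    if sim.deriv is not None:
        y = sim.deriv

        def design(c, w):
            return _deriv_design_matrix(wn, c, w, sim.sg_window, sim.sg_order)
    else:
        y = sim.values

        def design(c, w):
            return _design_matrix(wn, c, w)

    # solve on a unit-normalized signal so amplitude ratios (hence
    # fractions) are invariant to the spectrum's overall scale; the
    # active-set NNLS solver is exact, unlike iterative bounded lsq
    y_scale = float(np.linalg.norm(y))
    if y_scale == 0.0:
        amps = np.zeros(len(model.bands))
    else:
        amps = nnls(design(centers, widths), y / y_scale)[0] * y_scale
    if refine:
        n = len(model.bands)
        lo = np.concatenate([
            np.zeros(n),
            [b.center - b.center_tol for b in model.bands],
            [b.width_bounds[0] for b in model.bands],
        ])
        hi = np.concatenate([
            np.full(n, np.inf),
            [b.center + b.center_tol for b in model.bands],
            [b.width_bounds[1] for b in model.bands],
        ])
        x0 = np.concatenate([amps, centers, widths])
        x0 = np.clip(x0, lo, np.nextafter(hi, -np.inf))

        def resid(x):
            return design(x[n:2 * n], x[2 * n:]) @ x[:n] - y

        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-10, ftol=1e-10, max_nfev=200 * n)
        amps, centers, widths = sol.x[:n], sol.x[n:2 * n], sol.x[2 * n:]

    areas = amps * widths * np.sqrt(2.0 * np.pi)
    table = pd.DataFrame({
        "label": [b.label for b in model.bands],
        "structure_class": [b.structure_class for b in model.bands],
        "center": centers,
        "width": widths,
        "amplitude": amps,
        "area": areas,
    })
    mask = np.ones(len(model.bands), dtype=bool)
    if not include_side_chain:
        mask = table["structure_class"].to_numpy() != "side_chain"
    total = float(areas[mask].sum())
    fractions: dict[str, float] = {}
    for cls, cdf in table[mask].groupby("structure_class", sort=False):
        fractions[str(cls)] = float(cdf["area"].sum()) / total if total > 0 else np.nan
    return HOSComposition(fractions, table)


def _logistic(t: np.ndarray, y0: float, dy: float, tm: float, s: float) -> np.ndarray:
    return y0 + dy / (1.0 + np.exp((tm - t) / s))


def _fit_logistic_tm(t: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Logistic-midpoint Tm with a derivative-maximum fallback."""
    d = np.gradient(y, t)
    if d.size >= 5:
        d = np.convolve(d, np.ones(5) / 5, mode="same")
    tm0 = float(t[int(np.argmax(np.abs(d)))])
    p0 = (float(y[0]), float(y[-1] - y[0]), tm0, 2.0)
    try:
        popt, pcov = curve_fit(_logistic, t, y, p0=p0,
                               bounds=([-np.inf, -np.inf, t[0], 0.1],
                                       [np.inf, np.inf, t[-1], 30.0]),
                               maxfev=20000)
        return float(popt[2]), float(np.sqrt(pcov[2, 2])), "sigmoid"
    except (RuntimeError, ValueError):
        return tm0, np.nan, "derivative"


def melt_analysis(temperatures: np.ndarray, compositions: list[HOSComposition],
                  sim_spectra: list[SimilaritySpectrum] | None = None,
                  method: str = "sigmoid",
                  signal: str = "area",
                  flat_tol: float = 0.02) -> ThermalAnalysis:
    """Per-class and global melting temperatures from a thermal ramp.

    Each structure class's trace versus temperature is fit to a
    logistic sigmoid whose midpoint is the class Tm
    (``method="derivative"`` instead takes the temperature of maximum
    absolute rate of change).  ``signal`` selects the trace:
    ``"area"`` (default) uses the absolute fitted class band area,
    which isolates each class's transition; ``"fraction"`` uses the
    fractional contribution, which couples classes through the
    normalization (one class appears to melt when another grows).
    Classes whose trace varies by less than ``flat_tol`` of its
    magnitude over the ramp are flagged flat with undefined Tm.  The
    global Tm is fit the same way to a whole-spectrum dissimilarity
    trace, 1 − Pearson correlation with the lowest-temperature
    similarity spectrum, when spectra are provided.
    """
    t = np.asarray(temperatures, dtype=float)
    if t.size < 8:
        raise ValueError("need at least 8 temperatures spanning the transition")
    if t.size != len(compositions):
        raise ValueError("temperatures and compositions length mismatch")
    if signal not in ("area", "fraction"):
        raise ValueError(f"unknown signal {signal!r}")
    if signal == "area":
        classes = sorted({
            c for comp in compositions for c in comp.band_table["structure_class"]})
        traces = {
            cls: np.array([
                comp.band_table.loc[comp.band_table["structure_class"] == cls,
                                    "area"].sum()
                for comp in compositions
            ])
            for cls in classes
        }
    else:
        classes = sorted({c for comp in compositions for c in comp.fractions})
        traces = {
            cls: np.array([comp.fractions.get(cls, np.nan) for comp in compositions])
            for cls in classes
        }
    per_class: dict[str, ClassMelt] = {}
    for cls in classes:
        y = traces[cls]
        if not np.all(np.isfinite(y)):
            per_class[cls] = ClassMelt(np.nan, np.nan, "none", {"missing"})
            continue
        if float(np.ptp(y)) < flat_tol * max(float(np.max(np.abs(y))), 1e-12):
            per_class[cls] = ClassMelt(np.nan, np.nan, "none", {"flat"})
            continue
        if method == "derivative":
            d = np.gradient(y, t)
            if d.size >= 5:
                d = np.convolve(d, np.ones(5) / 5, mode="same")
            per_class[cls] = ClassMelt(float(t[int(np.argmax(np.abs(d)))]), np.nan, "derivative")
        else:
            tm, tm_se, how = _fit_logistic_tm(t, y)
            per_class[cls] = ClassMelt(tm, tm_se, how)

    global_tm, global_se = np.nan, np.nan
    if sim_spectra is not None:
        if len(sim_spectra) != t.size:
            raise ValueError("sim_spectra length mismatch")
        ref = sim_spectra[0].values
        dis = np.array([
            1.0 - (np.corrcoef(ref, s.values)[0, 1] if np.std(s.values) > 0 else 1.0)
            for s in sim_spectra
        ])
        global_tm, global_se, _ = _fit_logistic_tm(t, dis)
    return ThermalAnalysis(per_class, global_tm, global_se)


def _hyperbola(conc: np.ndarray, tm0: float, dmax: float, ec50: float) -> np.ndarray:
    return tm0 + dmax * conc / (conc + ec50)


def fit_ec50(points: list[tuple[float, float]]) -> EC50Fit:
    """Saturating (rectangular-hyperbola) fit of global Tm versus ligand concentration.

    ``points`` are (ligand concentration µM, global Tm °C) pairs; at
    least 4 concentrations including 0 are required.  When the maximal
    stabilization is indistinguishable from zero the fit is flagged
    ``no_stabilization`` and the EC50 is not identifiable.
    """
    conc = np.array([p[0] for p in points], dtype=float)
    tm = np.array([p[1] for p in points], dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if not np.any(conc == 0):
        raise ValueError("a zero-ligand (apo) point is required")
    flags: set = set()
    if float(np.ptp(tm)) < 1e-9:
        return EC50Fit(float(tm[0]), 0.0, np.nan, np.nan, {"no_stabilization"})
    pos = conc[conc > 0]
    p0 = (float(tm[conc == 0].mean()), float(np.max(tm) - np.min(tm)), float(np.median(pos)))
    popt, pcov = curve_fit(_hyperbola, conc, tm, p0=p0,
                           bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                           maxfev=20000)
    tm0, dmax, ec50 = (float(v) for v in popt)
    dmax_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    ec50_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    if not np.isfinite(dmax_se) or abs(dmax) < 1.96 * dmax_se:
        flags.add("no_stabilization")
    return EC50Fit(tm0, dmax, ec50, ec50_se, flags)


def run_thermal_ramp(series: IRSpectrumSeries, model: BandModel | None = None,
                     displacement_factor: float = DEFAULT_DISPLACEMENT_FACTOR,
                     method: str = "sigmoid",
                     signal: str = "area",
                     include_side_chain: bool = False,
                     ) -> tuple[list[HOSComposition], ThermalAnalysis, list[SimilaritySpectrum]]:
    """Full ramp pipeline: normalize, similarity-convert, deconvolve, melt-analyze.

    Band shapes are locked to the model across the ramp
    (``refine=False``) so that composition traces reflect amplitude
    changes rather than per-temperature shape drift.
    """
    model = model or default_band_model()
    sims, comps = [], []
    for row in series.absorbance:
        absolute = normalize_spectrum(row, displacement_factor)
        sim = similarity_spectrum(series.wavenumbers, absolute)
        sims.append(sim)
        comps.append(deconvolve_bands(sim, model, refine=False,
                                      include_side_chain=include_side_chain))
    analysis = melt_analysis(series.temperatures, comps, sims, method=method,
                             signal=signal)
    return comps, analysis, sims
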