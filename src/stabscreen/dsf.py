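"""Differential scanning fluorimetry (thermal shift) analysis.

A hydrophobic-sensitive dye reports protein unfolding as a rise in
fluorescence with temperature; past the unfolding transition the dye
dissociates again and the signal decays.  Each well's rising limb is fit
to a two-state Boltzmann sigmoid

    F(T) = f_pre + (f_post - f_pre) / (1 + exp((tm - T) / slope))

whose midpoint ``tm`` is the melting temperature.  Compounds are called
hits when their mean Tm exceeds the control mean by more than one
standard deviation of the compound-Tm distribution across the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "MeltCurve",
    "MeltFit",
    "HitTable",
    "boltzmann",
    "fit_melt_curve",
    "detect_biphasic",
    "fit_replicates",
    "call_hits",
]

#: fraction of the overall signal level below which a transition
#: amplitude is considered absent (no usable unfolding signal)
LOW_AMPLITUDE_FRAC = 0.05

#: minimum coefficient of determination for a trusted Boltzmann fit
MIN_R_SQUARED = 0.9

#: moving-average window (grid points) applied to the derivative before
#: biphasic peak counting
DERIV_SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class MeltCurve:
    """One well's fluorescence-versus-temperature trace."""

    well_id: str
    compound_id: str
    temperature: np.ndarray
    fluorescence: np.ndarray
    replicate_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise ValueError("temperature and fluorescence must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass
class MeltFit:
    """Fitted two-state transition parameters for one well."""

    tm: float
    slope: float
    f_pre: float
    f_post: float
    tm_se: float
    r_squared: float
    flags: set = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return np.isfinite(self.tm) and not ({"poor_fit", "low_amplitude"} & self.flags)


@dataclass
class HitTable:
    """Per-compound screen summary with the hit-calling threshold.

    ``table`` is indexed by compound id with columns mean_tm, tm_sd,
    delta_tm, hit, discard_reason.
    """

    table: pd.DataFrame
    control_mean_tm: float
    compound_tm_sd: float
    threshold: float

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "compound", out.index)
        out.to_csv(path, index=False)


def boltzmann(t: np.ndarray, f_pre: float, f_post: float, tm: float, slope: float) -> np.ndarray:
    """Two-state sigmoid used for the rising limb of a melt curve."""
    return f_pre + (f_post - f_pre) / (1.0 + np.exp((tm - t) / slope))


def _rising_window(curve: MeltCurve) -> slice:
    """Trace start up to and including the global fluorescence maximum.

    The Boltzmann model is invalid beyond the peak, where dye
    dissociation dominates.
    """
    stop = int(np.argmax(curve.fluorescence)) + 1
    return slice(0, stop)


def _smoothed_derivative(t: np.ndarray, f: np.ndarray, window: int = DERIV_SMOOTH_WINDOW) -> np.ndarray:
    d = np.gradient(f, t)
    if window > 1 and d.size >= window:
        kernel = np.ones(window) / window
        d = np.convolve(d, kernel, mode="same")
    return d


def derivative_tm(curve: MeltCurve) -> float:
    """Tm from the maximum of the smoothed derivative on the rising limb."""
    win = _rising_window(curve)
    t, f = curve.temperature[win], curve.fluorescence[win]
    d = _smoothed_derivative(t, f)
    return float(t[int(np.argmax(d))])


def fit_melt_curve(curve: MeltCurve, window_strategy: str = "to_max") -> MeltFit:
    """Fit one melt curve's rising limb to the Boltzmann sigmoid.

    Parameters
    ----------
    curve
        The raw trace; its temperature grid must be strictly increasing.
    window_strategy
        ``"to_max"`` (default) fits from the trace start to the global
        fluorescence maximum; ``"full"`` fits the whole trace (only
        sensible when no post-peak decay is present).

    Returns
    -------
    MeltFit
        Parameters with ``tm_se`` from the fit covariance and QC flags:
        ``low_amplitude`` when the signal rise is below
        ``LOW_AMPLITUDE_FRAC`` of the overall level (no Tm reported),
        ``poor_fit`` on non-convergence or r² < ``MIN_R_SQUARED``
        (Tm falls back to the derivative maximum), ``biphasic`` when the
        derivative shows two transitions.
    """
    if window_strategy not in ("to_max", "full"):
        raise ValueError(f"unknown window_strategy {window_strategy!r}")
    flags: set = set()
    full = curve.fluorescence
    scale = max(float(np.max(np.abs(full))), 1.0)
    if float(np.max(full) - np.min(full)) < LOW_AMPLITUDE_FRAC * scale:
        # no transition signal at all; windowing is meaningless
        flags.add("low_amplitude")
        return MeltFit(np.nan, np.nan, float(np.mean(full)), float(np.mean(full)),
                       np.nan, np.nan, flags)
    win = _rising_window(curve) if window_strategy == "to_max" else slice(None)
    t, f = curve.temperature[win], curve.fluorescence[win]
    if t.size < 10:
        raise ValueError("need at least 10 points on the rising limb")

    amplitude = float(np.max(f) - np.min(f))
    if amplitude < LOW_AMPLITUDE_FRAC * scale:
        flags.add("low_amplitude")
        return MeltFit(np.nan, np.nan, float(np.mean(f)), float(np.mean(f)),
                       np.nan, np.nan, flags)

    if detect_biphasic(curve):
        flags.add("biphasic")

    d = _smoothed_derivative(t, f)
    p0 = (float(np.min(f)), float(np.max(f)), float(t[int(np.argmax(d))]), 1.0)
    bounds = ([-np.inf, -np.inf, t[0], 0.05], [np.inf, np.inf, t[-1], 20.0])
    try:
        popt, pcov = curve_fit(boltzmann, t, f, p0=p0, bounds=bounds, maxfev=20000)
        f_pre, f_post, tm, slope = popt
        tm_se = float(np.sqrt(pcov[2, 2]))
        resid = f - boltzmann(t, *popt)
        ss_tot = float(np.sum((f - np.mean(f)) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        if not np.isfinite(r2) or r2 < MIN_R_SQUARED:
            flags.add("poor_fit")
    except (RuntimeError, ValueError):
        flags.add("poor_fit")
        return MeltFit(derivative_tm(curve), np.nan, float(np.min(f)),
                       float(np.max(f)), np.nan, np.nan, flags)
    return MeltFit(float(tm), float(slope), float(f_pre), float(f_post), tm_se, r2, flags)


def detect_biphasic(curve: MeltCurve, prominence_frac: float = 0.2,
                    min_width_C: float = 2.0) -> bool:
    """Whether the rising limb shows two distinct unfolding transitions.

    The first derivative of the rising region is smoothed with a
    5-point moving window; the curve is biphasic when it has at least
    two local maxima, each with height and prominence exceeding
    ``prominence_frac`` of the largest maximum.  A genuine transition's
    derivative peak spans several degrees, so peaks narrower than
    ``min_width_C`` (at half prominence) are ignored as noise.
    """
    win = _rising_window(curve)
    t, f = curve.temperature[win], curve.fluorescence[win]
    if t.size < DERIV_SMOOTH_WINDOW + 2:
        return False
    d = _smoothed_derivative(t, f)
    top = float(np.max(d))
    if top <= 0:
        return False
    step = float(np.median(np.diff(t)))
    peaks, _ = find_peaks(d, height=prominence_frac * top,
                          prominence=prominence_frac * top,
                          width=max(1.0, min_width_C / step))
    return peaks.size >= 2


def fit_replicates(curves: Sequence[MeltCurve]) -> dict[str, list[MeltFit]]:
    """Fit every curve and group the fits by compound id."""
    grouped: dict[str, list[MeltFit]] = {}
    for c in curves:
        grouped.setdefault(c.compound_id, []).append(fit_melt_curve(c))
    return grouped


def call_hits(
    fits: Mapping[str, Sequence[MeltFit]],
    control_id: str,
    reproducibility_tol: float = 2.0,
) -> HitTable:
    """Call screen hits against the control wells.

    A compound is discarded when any replicate is biphasic or poorly
    fit, or when its replicates disagree by more than
    ``reproducibility_tol`` °C.  The hit threshold is the control mean
    Tm plus one standard deviation of the mean-Tm distribution over the
    usable (non-discarded) compounds; a compound is a hit iff its mean
    Tm strictly exceeds the threshold and it was not discarded.
    """
    if control_id not in fits:
        raise ValueError(f"control compound {control_id!r} not present in fits")
    control_tms = [f.tm for f in fits[control_id] if f.usable]
    if not control_tms:
        raise ValueError("no usable control replicate fits")
    control_mean = float(np.mean(control_tms))

    rows = {}
    for compound, reps in fits.items():
        if compound == control_id:
            continue
        reason = None
        if any("biphasic" in f.flags for f in reps):
            reason = "biphasic"
        elif any(("poor_fit" in f.flags or "low_amplitude" in f.flags) for f in reps):
            reason = "poor_fit"
        tms = np.array([f.tm for f in reps if np.isfinite(f.tm)])
        if tms.size == 0:
            reason = reason or "poor_fit"
            mean_tm, tm_sd = np.nan, np.nan
        else:
            mean_tm = float(np.mean(tms))
            tm_sd = float(np.std(tms, ddof=1)) if tms.size > 1 else 0.0
            if reason is None and tms.size > 1 and float(np.ptp(tms)) > reproducibility_tol:
                reason = "irreproducible"
        rows[compound] = {"mean_tm": mean_tm, "tm_sd": tm_sd, "discard_reason": reason}

    table = pd.DataFrame.from_dict(rows, orient="index")
    usable = table.loc[table["discard_reason"].isna(), "mean_tm"].dropna()
    compound_sd = float(usable.std(ddof=1)) if usable.size > 1 else 0.0
    threshold = control_mean + compound_sd
    table["delta_tm"] = table["mean_tm"] - control_mean
    table["hit"] = (table["mean_tm"] > threshold) & table["discard_reason"].isna()
    table = table[["mean_tm", "tm_sd", "delta_tm", "hit", "discard_reason"]]
    table.index.name = "compound"
    return HitTable(table, control_mean, compound_sd, float(threshold))
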