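"""Fluorescence-trace preprocessing.

Raw ROI fluorescence from calcium imaging is converted to the two
dimensionless forms used in analysis: the min-max scaled dF/F_max
(``(F - F_min)/(F_max - F_min)``, region-wise 0..1) and the baseline-relative
dF/F_0 (``(F - F_0)/F_0`` with F_0 the mean fluorescence over a 5-s window
before stimulus onset).  Background subtraction and single-exponential
photobleaching correction precede normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateNormalizationError, InvalidBaselineError

__all__ = [
    "RawFluorescenceTrace", "NormalizedTrace",
    "subtract_background", "bleach_correct",
    "normalize_minmax", "normalize_f0",
]

#: Baseline window length (s) for F_0, and the minimum acceptable window if
#: the trace starts closer than that to stimulus onset.
F0_WINDOW = 5.0
F0_MIN_WINDOW = 1.0


@dataclass(frozen=True)
class RawFluorescenceTrace:
    """Fluorescence from one ROI: time (s), F (arbitrary units), background."""

    time: np.ndarray
    F: np.ndarray
    region: str = "soma"
    background: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.F, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("time and F must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("F must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "F", f)


@dataclass(frozen=True)
class NormalizedTrace:
    """Dimensionless trace with its normalization tag and metadata."""

    time: np.ndarray
    value: np.ndarray
    method: str  # "minmax" | "f0"
    meta: dict


def subtract_background(trace: RawFluorescenceTrace) -> RawFluorescenceTrace:
    """Subtract the per-trace scalar background from every sample."""
    if trace.background > trace.F.min():
        warnings.warn(
            f"background {trace.background:g} exceeds min(F); corrected trace "
            "goes negative", stacklevel=2)
    return replace(trace, F=trace.F - trace.background, background=0.0)


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    return (time >= t0) & (time < t1)


def bleach_correct(trace: RawFluorescenceTrace,
                   pre_window: tuple[float, float],
                   post_window: tuple[float, float],
                   mode: str = "divide") -> RawFluorescenceTrace:
    """Remove photobleaching by a single exponential fitted outside the stimulus.

    One curve a*exp(-b t) is least-squares fitted jointly to the samples in
    the pre- and post-stimulation windows (both assumed at baseline).  With
    ``mode="divide"`` the trace is divided by exp(-b t), so the fitted curve
    becomes the constant a; ``mode="subtract"`` removes the fitted trend
    additively (F - a exp(-b t) + a).  If the fit fails or finds a negative
    decay rate, the input is returned unchanged with a warning.
    """
    if mode not in ("divide", "subtract"):
        raise ValueError("mode must be 'divide' or 'subtract'")
    mask = _window_mask(trace.time, pre_window) | _window_mask(trace.time, post_window)
    if mask.sum() < 3:
        warnings.warn("too few baseline samples for bleach fit; trace unchanged",
                      stacklevel=2)
        return trace
    t_fit, f_fit = trace.time[mask], trace.F[mask]
    try:
        # log-linear starting point, then proper least squares on the exponential
        pos = f_fit > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t_fit[pos], np.log(f_fit[pos]), 1)
            p0 = (float(np.exp(intercept)), float(-slope))
        else:
            p0 = (float(f_fit.mean()), 0.0)
        (a, b), _ = curve_fit(lambda t, a, b: a * np.exp(-b * t),
                              t_fit, f_fit, p0=p0, maxfev=10_000)
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"bleach fit did not converge ({exc}); trace unchanged",
                      stacklevel=2)
        return trace
    if b < 0:
        warnings.warn("bleach fit found a brightening trend (b < 0); "
                      "trace unchanged", stacklevel=2)
        return trace
    decay = np.exp(-b * trace.time)
    if mode == "divide":
        corrected = trace.F / decay
    else:
        corrected = trace.F - a * decay + a
    return replace(trace, F=corrected)


def normalize_minmax(trace: RawFluorescenceTrace) -> NormalizedTrace:
    """(F - F_min)/(F_max - F_min): region-wise linear scaling to [0, 1]."""
    f_min, f_max = float(trace.F.min()), float(trace.F.max())
    if f_max <= f_min:
        raise DegenerateNormalizationError(
            "constant trace: min-max normalization undefined")
    return NormalizedTrace(trace.time.copy(), (trace.F - f_min) / (f_max - f_min),
                           "minmax", {"F_min": f_min, "F_max": f_max,
                                      "region": trace.region})


def normalize_f0(trace: RawFluorescenceTrace, stim_onset: float,
                 window: float = F0_WINDOW) -> NormalizedTrace:
    """(F - F_0)/F_0 with F_0 the mean over ``window`` seconds before onset.

    If the trace starts less than ``window`` seconds before the stimulus, all
    available pre-onset samples are used, down to a floor of 1 s.
    """
    t0 = stim_onset - window
    if t0 < trace.time[0]:
        avail = stim_onset - trace.time[0]
        if avail < F0_MIN_WINDOW:
            raise InvalidBaselineError(
                f"only {avail:g} s of pre-stimulus baseline available "
                f"(minimum {F0_MIN_WINDOW:g} s)")
        warnings.warn(f"baseline window shortened to {avail:g} s", stacklevel=2)
        t0 = trace.time[0]
    mask = (trace.time >= t0) & (trace.time < stim_onset)
    if not mask.any():
        raise InvalidBaselineError("no samples in the baseline window")
    f0 = float(trace.F[mask].mean())
    if f0 <= 0:
        raise InvalidBaselineError(f"non-positive baseline F_0 = {f0:g}")
    return NormalizedTrace(trace.time.copy(), (trace.F - f0) / f0, "f0",
                           {"F_0": f0, "region": trace.region})
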