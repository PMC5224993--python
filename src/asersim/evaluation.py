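"""Model evaluation: VAF, temporal response metrics, sigmoid peak transfer.

VAF (variance accounted for) scores how much of the variance of a measured
trace a simulation explains: ``VAF = 100 * (1 - var(actual - simulated) /
var(actual))``, 100% at a perfect fit, possibly negative for a bad one.
The temporal metrics quantify the characteristic ASER response shape: the
half-rise time after stimulus onset, the half-decay during the sustained
stimulus, and the return to baseline after the upstep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import UndefinedVAFError
from .stimulus import StimulusProtocol

__all__ = [
    "vaf", "TemporalMetrics", "temporal_metrics", "peak_response",
    "SigmoidTransfer", "fit_sigmoid_transfer",
]

#: Half-width of the "back at baseline" band, as a fraction of peak amplitude.
BASELINE_BAND = 0.05


def vaf(actual: np.ndarray, simulated: np.ndarray,
        denominator: str = "actual") -> float:
    """Percent variance accounted for by the simulation.

    ``denominator`` selects which trace's variance normalizes the residual;
    the default ("actual") keeps VAF = 100 exactly at a perfect fit.
    """
    actual = np.asarray(actual, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if actual.shape != simulated.shape:
        raise UndefinedVAFError("traces must have equal length")
    ref = actual if denominator == "actual" else simulated
    denom = float(np.var(ref))
    if denom == 0.0:
        raise UndefinedVAFError("reference trace has zero variance")
    return 100.0 * (1.0 - float(np.var(actual - simulated)) / denom)


def _cross_time(time: np.ndarray, value: np.ndarray, level: float,
                rising: bool) -> float | None:
    """First time the trace crosses ``level``, linearly interpolated."""
    if rising:
        hit = value >= level
    else:
        hit = value <= level
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0 or value[i] == value[i - 1]:
        return float(time[i])
    frac = (level - value[i - 1]) / (value[i] - value[i - 1])
    return float(time[i - 1] + frac * (time[i] - time[i - 1]))


@dataclass(frozen=True)
class TemporalMetrics:
    """Timing metrics of one response; NaN fields when undefined."""

    t_half_rise: float
    decay_during_stimulus: float
    decay_to_baseline: float
    peak: float
    baseline: float
    defined: bool = True


def temporal_metrics(time: np.ndarray, value: np.ndarray,
                     protocol: StimulusProtocol,
                     baseline_band: float = BASELINE_BAND) -> TemporalMetrics:
    """Half-rise, in-stimulus half-decay, and post-upstep return to baseline.

    peak = maximum within the stimulation epoch; baseline = mean pre-onset
    value.  t_half_rise is the time from onset to the half-peak crossing;
    decay_during_stimulus is the time from the peak until the trace falls
    halfway toward its pre-upstep level; decay_to_baseline is the time after
    the epoch end until the trace first re-enters a band of
    ``baseline_band * (peak - baseline)`` around the baseline.
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    onset, offset = protocol.epoch_start, protocol.epoch_end
    pre = value[time < onset]
    baseline = float(pre.mean()) if pre.size else 0.0
    in_epoch = (time >= onset) & (time <= offset)
    if not in_epoch.any():
        raise ValueError("trace does not cover the stimulation epoch")
    seg_t, seg_v = time[in_epoch], value[in_epoch]
    i_peak = int(np.argmax(seg_v))
    peak = float(seg_v[i_peak])
    t_peak = float(seg_t[i_peak])
    amplitude = peak - baseline
    if amplitude <= 0:
        nan = float("nan")
        return TemporalMetrics(nan, nan, nan, peak, baseline, defined=False)

    t_half = _cross_time(seg_t, seg_v, baseline + 0.5 * amplitude, rising=True)
    t_half_rise = t_half - onset if t_half is not None else float("nan")

    pre_upstep = float(seg_v[-1])
    target = pre_upstep + 0.5 * (peak - pre_upstep)
    after_peak = seg_t >= t_peak
    t_fall = _cross_time(seg_t[after_peak], seg_v[after_peak], target, rising=False)
    decay_during = t_fall - t_peak if t_fall is not None else float("nan")

    post = time >= offset
    band = baseline_band * amplitude
    t_base = _cross_time(time[post], np.abs(value[post] - baseline), band,
                         rising=False)
    decay_after = t_base - offset if t_base is not None else float("nan")

    return TemporalMetrics(t_half_rise, decay_during, decay_after,
                           peak, baseline, defined=True)


def peak_response(time: np.ndarray, value: np.ndarray,
                  epoch: tuple[float, float]) -> float:
    """Maximum within the stimulation epoch minus the pre-onset baseline."""
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    onset, offset = epoch
    pre = value[time < onset]
    baseline = float(pre.mean()) if pre.size else 0.0
    mask = (time >= onset) & (time <= offset)
    if not mask.any():
        raise ValueError("epoch outside trace span")
    return float(value[mask].max()) - baseline


_FORMS = {
    "logistic": lambda s, P, k, p0: P / (1.0 + np.exp(-k * (s - p0))),
    "tanh": lambda s, P, k, p0: 0.5 * P * (1.0 + np.tanh(k * (s - p0))),
    "hill": lambda s, P, k, p0: P * np.power(np.maximum(s, 1e-12), k)
            / (np.power(np.maximum(p0, 1e-12), k) + np.power(np.maximum(s, 1e-12), k)),
}


@dataclass(frozen=True)
class SigmoidTransfer:
    """Saturating stimulus-to-peak transfer: maximum, steepness, midpoint."""

    P_max: float
    k: float
    p0: float
    form: str = "logistic"
    rms_residual: float = 0.0
    poor_fit: bool = False

    def __call__(self, stimulus_sizes) -> np.ndarray:
        return _FORMS[self.form](np.asarray(stimulus_sizes, dtype=float),
                                 self.P_max, self.k, self.p0)


def fit_sigmoid_transfer(stimulus_sizes, peaks, form: str = "logistic",
                         ) -> tuple[SigmoidTransfer, np.ndarray]:
    """Fit a saturating transfer between stimulus size and peak response.

    The measured peak-vs-downstep relation saturates while the model's peak
    grows linearly with input, so mapping model peaks through this fitted
    sigmoid reconciles the two.  Returns the fitted transfer and the model
    peaks passed through it.  Fits with a large residual relative to the
    response range (e.g. strictly linear data) are flagged ``poor_fit``.
    """
    sizes = np.asarray(stimulus_sizes, dtype=float)
    pk = np.asarray(peaks, dtype=float)
    if sizes.size < 4 or np.unique(sizes).size != sizes.size:
        raise ValueError("need >= 4 (size, peak) pairs with distinct sizes")
    if form not in _FORMS:
        raise ValueError(f"unknown sigmoid form {form!r}")
    func = _FORMS[form]
    p0 = (float(pk.max()), 1.0, float(np.median(sizes)))
    bounds = ([1e-12, 1e-6, -np.inf], [np.inf, 1e3, np.inf])
    try:
        popt, _ = curve_fit(func, sizes, pk, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"sigmoid fit did not converge (residuals at start: "
            f"{np.abs(pk - func(sizes, *p0)).tolist()})") from exc
    fitted = func(sizes, *popt)
    rms = float(np.sqrt(np.mean((fitted - pk) ** 2)))
    span = float(pk.max() - pk.min()) or 1.0
    # poor fit: large residual, steepness at its bounds, or a midpoint pushed
    # outside the sampled range (the small-k limit where a logistic
    # degenerates to a straight line)
    s_lo, s_hi = float(sizes.min()), float(sizes.max())
    s_span = s_hi - s_lo
    poor = (rms > 0.02 * span
            or popt[1] >= 0.99 * bounds[1][1] or popt[1] <= 2 * bounds[0][1]
            or not (s_lo - 0.5 * s_span <= popt[2] <= s_hi + 0.5 * s_span))
    transfer = SigmoidTransfer(float(popt[0]), float(popt[1]), float(popt[2]),
                               form=form, rms_residual=rms, poor_fit=poor)
    return transfer, transfer(pk)
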