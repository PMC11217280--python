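"""Response-timing descriptors and relative firing-rate modulation.

All descriptors operate on across-rep mean PSTHs.  The "1 SD" criterion
used for latencies and decay refers to the standard deviation of the mean
PSTH's baseline bins (the 3 s preceding light onset).  Timing outputs are
quantised to the bin width of the trace they are measured on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "DynamicsResult",
    "baseline_stats",
    "latency_late",
    "latency_on_peak",
    "decay_time",
    "relative_change",
    "smooth_trace",
    "find_local_extrema",
]


@dataclass
class DynamicsResult:
    unit_id: str
    latency_late_s: float | None
    latency_on_peak_s: float | None
    decay_s: float
    decay_censored: bool
    m_early_pct: float | None
    m_late_pct: float | None


def baseline_stats(mean_trace: np.ndarray, bin_s: float, window_start_s: float,
                   baseline_window=(-3.0, 0.0)) -> tuple[float, float]:
    """Mean and SD of the mean-PSTH bins in the pre-onset baseline window."""
    i0 = int(round((baseline_window[0] - window_start_s) / bin_s))
    i1 = int(round((baseline_window[1] - window_start_s) / bin_s))
    seg = np.asarray(mean_trace, dtype=float)[i0:i1]
    return float(seg.mean()), float(seg.std(ddof=0))


def latency_late(
    mean_trace: np.ndarray,
    bin_s: float,
    window_start_s: float = -4.0,
    direction: int = 1,
    stim_s: float = 10.0,
    search_from_s: float = 1.0,
) -> float | None:
    """Onset latency (s) of the late (sustained) response component.

    The late component is localised as the contiguous epoch within
    [search_from_s, stim_s] whose signed deviation from baseline exceeds
    1 baseline SD with the largest total deviation; the latency is the
    start of the first-crossing run containing it (walking back while the
    deviation stays above 1 SD).  For suppressed units the crossing is
    sought downward.  Returns None when the trace never crosses.
    """
    trace = np.asarray(mean_trace, dtype=float)
    base_mean, base_sd = baseline_stats(trace, bin_s, window_start_s)
    dev = direction * (trace - base_mean)
    i_lo = int(round((search_from_s - window_start_s) / bin_s))
    i_hi = int(round((stim_s - window_start_s) / bin_s))
    above = dev > base_sd
    # runs of above-threshold bins intersecting [i_lo, i_hi)
    best_score, best_start = None, None
    i = 0
    n = len(trace)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j > i_lo and i < i_hi:  # run overlaps the late search window
            score = dev[max(i, i_lo):min(j, i_hi)].sum()
            if best_score is None or score > best_score:
                best_score, best_start = score, i
        i = j
    if best_start is None:
        return None
    t = window_start_s + best_start * bin_s
    return float(max(t, 0.0))


def latency_on_peak(
    mean_trace_10ms: np.ndarray,
    bin_s: float = 0.01,
    window_start_s: float = -4.0,
    search_s: float = 2.0,
) -> float | None:
    """Latency (s) of the ON peak: time of the extremum within the first 2 s.

    Computed on a high-resolution (10 ms) mean PSTH.  The peak is valid only
    if it exceeds the baseline mean by more than 1 baseline SD; otherwise
    the latency is undefined (None).
    """
    trace = np.asarray(mean_trace_10ms, dtype=float)
    base_mean, base_sd = baseline_stats(trace, bin_s, window_start_s)
    i0 = int(round((0.0 - window_start_s) / bin_s))
    i1 = int(round((search_s - window_start_s) / bin_s))
    seg = trace[i0:i1]
    if len(seg) == 0:
        return None
    i_peak = int(np.argmax(seg))
    if seg[i_peak] <= base_mean + base_sd:
        return None
    return float(i_peak * bin_s)


def decay_time(
    mean_trace: np.ndarray,
    bin_s: float,
    window_start_s: float = -4.0,
    stim_s: float = 10.0,
    post_s: float = 6.0,
    min_hold_bins: int = 2,
) -> tuple[float, bool]:
    """Time (s) after light offset for the mean FR to return to baseline.

    Return is declared at the first post-offset bin whose rate re-enters
    the baseline +/- 1 SD band and stays inside for at least
    ``min_hold_bins`` consecutive bins.  If no such return occurs within the
    ``post_s`` window, the decay is censored at ``post_s``.
    """
    trace = np.asarray(mean_trace, dtype=float)
    base_mean, base_sd = baseline_stats(trace, bin_s, window_start_s)
    i_off = int(round((stim_s - window_start_s) / bin_s))
    i_end = int(round((stim_s + post_s - window_start_s) / bin_s))
    inside = np.abs(trace[i_off:i_end] - base_mean) <= base_sd
    run = 0
    for i, ok in enumerate(inside):
        run = run + 1 if ok else 0
        if run >= min_hold_bins:
            return float((i - min_hold_bins + 1) * bin_s), False
    return float(post_s), True


def relative_change(fr0: float, fr_window: float) -> float | None:
    """Percent FR modulation relative to baseline: 100 * (FRw - FR0) / FR0.

    Zero means no change; positive/negative an increase/decrease.  With a
    zero baseline the quantity is undefined and None is returned.
    """
    if fr0 == 0:
        return None
    return float(100.0 * (fr_window - fr0) / fr0)


def smooth_trace(trace: np.ndarray, window_s: float = 5.0, bin_s: float = 1.0) -> np.ndarray:
    """Centered moving average; edges use truncated windows (sum-preserving
    in the interior, unchanged for constant traces)."""
    x = np.asarray(trace, dtype=float)
    w = int(round(window_s / bin_s))
    if w > len(x):
        raise ValueError("smoothing window exceeds trace length")
    if w <= 1:
        return x.copy()
    half = w // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def find_local_extrema(trace: np.ndarray, prominence: float = 0.0):
    """Interior local maxima and minima of a (smoothed) trace.

    Returns (maxima indices, minima indices); with prominence 0 every
    interior first-difference sign change is reported.
    """
    x = np.asarray(trace, dtype=float)
    kwargs = {"prominence": prominence} if prominence > 0 else {}
    maxima, _ = find_peaks(x, **kwargs)
    minima, _ = find_peaks(-x, **kwargs)
    return maxima, minima
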