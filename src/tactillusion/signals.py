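"""Force and laser-displacement trace processing.

Raw load-cell and laser-triangulation readings are smoothed with a
100-sample moving-average filter, the loading ramp of each force trace is
segmented from the first-order derivative, the force-rate is the
ordinary-least-squares slope over that segment, and the net fingertip
displacement is the absolute difference of the displacement channel
between movement initiation and conclusion (taken from the time-aligned
force ramp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

__all__ = [
    "Trace",
    "RampSegment",
    "smooth",
    "process_force_trace",
    "extract_ramp",
    "force_rate",
    "net_displacement",
]

#: default sensor sample rates (Hz): passive-stage load cell, active load
#: cell, laser displacement sensor
DEFAULT_RATES = {"passive_force": 300.0, "active_force": 80.0, "laser": 1500.0}

DEFAULT_SMOOTH_WINDOW = 100


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled sensor time series.

    ``values`` are N for force channels and mm for displacement channels.
    """

    timestamps: np.ndarray  # seconds
    values: np.ndarray
    sample_rate: float  # Hz

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        if t.size < 2 or v.size != t.size:
            raise ValueError("Trace needs >= 2 aligned samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if dt.max() > 1.01 * dt.min():
            raise ValueError("timestamps must be uniform within 1%")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @staticmethod
    def from_values(values, sample_rate: float) -> "Trace":
        values = np.asarray(values, dtype=float)
        t = np.arange(values.size) / float(sample_rate)
        return Trace(t, values, float(sample_rate))


@dataclass(frozen=True)
class RampSegment:
    """A contiguous loading-ramp interval of a force trace."""

    start_index: int
    end_index: int  # inclusive
    slope: float  # N/s
    r2: float

    def __post_init__(self):
        if self.start_index >= self.end_index:
            raise ValueError("ramp segment needs start < end")


def smooth(trace: Trace, window: int = DEFAULT_SMOOTH_WINDOW) -> Trace:
    """Moving-average filter with a window of ``window`` readings.

    Interior samples average a centred window of exactly ``window``
    neighbours; near the edges the window shrinks symmetrically so the
    output has the same length as the input and constant traces pass
    through unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(trace)
    if window > n:
        raise ValueError(f"window ({window}) exceeds trace length ({n})")
    left = (window - 1) // 2
    right = window - 1 - left
    csum = np.concatenate([[0.0], np.cumsum(trace.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
    return Trace(trace.timestamps, out, trace.sample_rate)


def extract_ramp(
    trace: Trace,
    threshold_fraction: float = 0.2,
    min_run: int = 2,
) -> RampSegment:
    """Segment the loading ramp of a (smoothed) force trace.

    Computes first differences and keeps the longest contiguous run where
    the derivative exceeds ``threshold_fraction`` of the peak positive
    derivative.  Only the ascending limb qualifies (positive derivative),
    so the descending limb of a triangle-wave protocol is excluded.

    Raises
    ------
    ValueError
        If no super-threshold run of at least ``min_run`` samples exists
        (e.g. a constant trace).
    """
    dv = np.diff(trace.values)
    peak = dv.max()
    if peak <= 0:
        raise ValueError("no ascending ramp found in trace")
    mask = dv > threshold_fraction * peak
    # longest contiguous True run
    best_len, best_start = 0, -1
    run_len, run_start = 0, 0
    for i, flag in enumerate(mask):
        if flag:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len + 1 < max(min_run, 2):
        raise ValueError("no ramp run of sufficient length found")
    start, end = best_start, best_start + best_len  # diff index i spans samples i..i+1
    seg_t = trace.timestamps[start:end + 1]
    seg_v = trace.values[start:end + 1]
    fit = linregress(seg_t, seg_v)
    return RampSegment(start_index=int(start), end_index=int(end),
                       slope=float(fit.slope), r2=float(fit.rvalue**2))


def force_rate(segment: RampSegment, trace: Trace) -> float:
    """OLS slope (N/s) of force against time over ``segment``."""
    t = trace.timestamps[segment.start_index:segment.end_index + 1]
    v = trace.values[segment.start_index:segment.end_index + 1]
    if t.size < 2 or t[-1] <= t[0]:
        raise ValueError("degenerate time span for force-rate regression")
    return float(linregress(t, v).slope)


def process_force_trace(force: Trace, displacement: Trace | None = None,
                        window: int = DEFAULT_SMOOTH_WINDOW,
                        threshold_fraction: float = 0.2) -> dict:
    """Full per-trial trace analysis: smoothing, ramp, rate, displacement.

    The force trace is smoothed (the window shrinks to a third of the
    trace for short recordings), the loading ramp segmented, and the
    force-rate regressed over the ramp after trimming one filter window
    from each end — the moving average rounds the ramp shoulders over
    half a window on each side, and including those samples biases the
    fitted slope low.  When a time-aligned displacement trace is given,
    the net fingertip displacement is evaluated between the ramp
    boundaries mapped through the (possibly different) sample rate.

    Returns a dict with ``force_rate_Nps``, ``r2``, the ramp segment, and
    ``displacement_mm`` (None without a displacement trace).
    """
    window_eff = min(window, max(3, len(force) // 3))
    sm = smooth(force, window_eff)
    seg = extract_ramp(sm, threshold_fraction=threshold_fraction)
    run = seg.end_index - seg.start_index + 1
    trim = min(window_eff, (run - max(2, run // 5)) // 2)
    trimmed = RampSegment(
        start_index=seg.start_index + max(trim, 0),
        end_index=seg.end_index - max(trim, 0),
        slope=seg.slope, r2=seg.r2)
    rate = force_rate(trimmed, sm)
    t_fit = sm.timestamps[trimmed.start_index:trimmed.end_index + 1]
    v_fit = sm.values[trimmed.start_index:trimmed.end_index + 1]
    r2 = float(linregress(t_fit, v_fit).rvalue ** 2)
    disp = None
    if displacement is not None:
        t0 = force.timestamps[seg.start_index]
        t1 = force.timestamps[seg.end_index]
        i0 = int(np.argmin(np.abs(displacement.timestamps - t0)))
        i1 = int(np.argmin(np.abs(displacement.timestamps - t1)))
        sm_d = smooth(displacement, min(window, max(1, len(displacement) // 3)))
        disp = net_displacement(sm_d, i0, i1)
    return {"force_rate_Nps": rate, "r2": r2, "segment": trimmed,
            "displacement_mm": disp}


def net_displacement(trace: Trace, start_index: int, end_index: int) -> float:
    """|displacement(end) - displacement(start)| in mm.

    ``start_index``/``end_index`` mark movement initiation and conclusion,
    normally taken from the ramp boundaries of the time-aligned force
    trace (rescaled to this trace's sample rate by the caller when the
    rates differ).
    """
    n = len(trace)
    if not (0 <= start_index < n and 0 <= end_index < n):
        raise ValueError("movement indices out of range")
    return float(abs(trace.values[end_index] - trace.values[start_index]))
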