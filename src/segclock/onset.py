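"""Mesp differentiation-marker signal-onset calling.

A cell is classified as having a *clear rise* when its smoothed maximum
exceeds the baseline by both a noise criterion and a relative criterion;
onset is the earliest sustained crossing of a noise-scaled threshold above
baseline.  All constants are explicit configuration: the procedure is this
module's documented operationalisation of by-eye onset scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trace import CycleTable, Trace, _moving_median, robust_noise_sd

__all__ = [
    "OnsetParams",
    "OnsetCall",
    "classify_clear_rise",
    "detect_onset",
    "onset_vs_arrest",
    "onset_from_roi_max",
]


@dataclass(frozen=True)
class OnsetParams:
    """Thresholds of the sustained-rise onset caller."""

    baseline_frames: int = 6  # B: frames defining the baseline median
    noise_k: float = 5.0  # clear rise needs max - baseline >= k * noise
    rel_f: float = 0.5  # ... or >= f * baseline (whichever is larger)
    onset_k: float = 3.0  # onset threshold: baseline + k_on * noise
    sustain_frames: int = 3  # m consecutive frames above threshold
    smooth_window: int = 3  # moving-median window
    noise_floor: float = 1e-6
    #: sub-frame refinement: linearly interpolate the threshold crossing
    #: between the last sub-threshold and first supra-threshold frames,
    #: removing the half-frame quantisation bias
    interpolate: bool = True


@dataclass(frozen=True)
class OnsetCall:
    onset_time: Optional[float]
    clear_rise: bool
    baseline: float
    rise_magnitude: float
    inconsistent: bool = False


def _baseline_noise(trace: Trace, params: OnsetParams) -> tuple[float, float, np.ndarray]:
    v = trace.values
    if len(v) < params.baseline_frames:
        raise ValueError("trace shorter than the baseline segment")
    base_seg = v[: params.baseline_frames]
    baseline = float(np.median(base_seg))
    noise = max(robust_noise_sd(base_seg), params.noise_floor)
    smoothed = _moving_median(v, params.smooth_window)
    return baseline, noise, smoothed


def classify_clear_rise(mesp: Trace, params: OnsetParams | None = None
                        ) -> tuple[bool, float]:
    """Clear-rise flag and rise magnitude (smoothed max minus baseline)."""
    params = params or OnsetParams()
    if len(mesp) < 20:
        raise ValueError("need at least 20 samples to classify a rise")
    baseline, noise, smoothed = _baseline_noise(mesp, params)
    rise = float(smoothed.max() - baseline)
    threshold = max(params.noise_k * noise, params.rel_f * abs(baseline))
    return rise >= threshold and rise > 0, max(rise, 0.0)


def detect_onset(mesp: Trace, params: OnsetParams | None = None) -> OnsetCall:
    """Call onset as the earliest sustained crossing above baseline.

    Requires a clear rise; if the sustained-crossing criterion is never met
    despite the rise classification, the call is flagged inconsistent
    (forcing a parameter review) rather than silently dropped.
    """
    params = params or OnsetParams()
    clear, rise = classify_clear_rise(mesp, params)
    baseline, noise, smoothed = _baseline_noise(mesp, params)
    if not clear:
        return OnsetCall(onset_time=None, clear_rise=False,
                         baseline=baseline, rise_magnitude=rise)
    thresh = baseline + params.onset_k * noise
    above = smoothed > thresh
    m = params.sustain_frames
    for i in range(len(above) - m + 1):
        if above[i:i + m].all():
            t_on = float(mesp.times[i])
            if params.interpolate and i > 0 and smoothed[i] > smoothed[i - 1]:
                frac = (thresh - smoothed[i - 1]) / (smoothed[i] - smoothed[i - 1])
                t_on = float(mesp.times[i - 1] + frac * mesp.frame_interval)
            return OnsetCall(onset_time=t_on, clear_rise=True,
                             baseline=baseline, rise_magnitude=rise)
    return OnsetCall(onset_time=None, clear_rise=True, baseline=baseline,
                     rise_magnitude=rise, inconsistent=True)


def onset_vs_arrest(cycle_table: CycleTable, call: OnsetCall) -> Optional[float]:
    """Signed delay of marker onset relative to clock arrest, minutes.

    None when either event is absent (the caller tallies such cells)."""
    if call.onset_time is None or cycle_table.n_peaks < 1:
        return None
    return float(call.onset_time - cycle_table.last_peak_time)


def onset_delay_summary(tables: Sequence[CycleTable],
                        calls: Sequence[OnsetCall]) -> pd.DataFrame:
    """Cohort Δt = onset - last peak table; excluded cells are counted via
    the has_delay column."""
    rows = []
    for tab, call in zip(tables, calls):
        delta = onset_vs_arrest(tab, call)
        rows.append({"cell_id": tab.cell_id,
                     "delta_min": delta if delta is not None else np.nan,
                     "has_delay": delta is not None,
                     "no_onset": call.onset_time is None})
    return pd.DataFrame(rows)


def onset_from_roi_max(mesp_stack: np.ndarray,
                       roi: tuple[int, int, int, int],
                       frame_interval: float,
                       imaging_start_offset: float = 0.0) -> Trace:
    """Per-frame maximum intensity inside a fixed ROI (x, y, w, h; 0-based,
    half-open), as used for the clock-disabled arm."""
    stack = np.asarray(mesp_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a T x H x W stack")
    x, y, w, h = roi
    T, H, W = stack.shape
    if not (0 <= x < x + w <= W and 0 <= y < y + h <= H):
        raise ValueError("ROI outside image bounds")
    if w == 0 or h == 0:
        raise ValueError("empty ROI")
    vals = stack[:, y:y + h, x:x + w].max(axis=(1, 2))
    times = imaging_start_offset + frame_interval * np.arange(T)
    return Trace(times=times, values=vals, frame_interval=frame_interval,
                 t0_offset=imaging_start_offset)
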