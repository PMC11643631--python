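"""Her1 trace quantification: oscillatory window, peak detection,
sub-frame parabolic refinement, cycle tables, censoring and alignment.

A *cycle* is the interval between two successive refined peaks; with K
detected peaks a cell has K-1 periods and K-2 successive-cycle ratio pairs
(period ratio cycle n+1 / cycle n, and peak-intensity ratio over the same
pair of cycles).  The last refined peak marks clock arrest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Trace",
    "PeakParams",
    "PeakList",
    "CycleTable",
    "WindowPolicy",
    "NonOscillatoryError",
    "detect_oscillatory_window",
    "find_peaks",
    "refine_peak_parabolic",
    "build_cycle_table",
    "analyze_trace",
    "apply_left_censoring",
    "align_by_first_peak",
    "cycle_tables_to_frame",
    "ratio_pairs",
    "robust_noise_sd",
]


class NonOscillatoryError(ValueError):
    """Raised when no oscillatory window can be found in a trace."""


@dataclass(frozen=True)
class Trace:
    """A sampled single-cell intensity time series for one channel.

    ``times`` are absolute minutes (post-dissociation in culture, movie time
    in the embryo) on a uniform grid of spacing ``frame_interval``.
    """

    times: np.ndarray
    values: np.ndarray
    frame_interval: float
    t0_offset: float = 0.0
    censor_left: bool = False

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, self.frame_interval, rtol=1e-6, atol=1e-6):
                raise ValueError("times must be uniformly spaced at frame_interval")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    def shifted(self, offset: float) -> "Trace":
        return dataclasses.replace(self, values=self.values + offset)

    def scaled(self, factor: float) -> "Trace":
        return dataclasses.replace(self, values=self.values * factor)

    def interpolate_gaps(self, max_gap: int = 2) -> "Trace":
        """Linearly fill NaN runs of length <= max_gap; longer runs raise."""
        v = self.values.copy()
        isnan = np.isnan(v)
        if not isnan.any():
            return self
        # run-length check
        run = 0
        for flag in isnan:
            run = run + 1 if flag else 0
            if run > max_gap:
                raise ValueError(f"gap longer than {max_gap} frames")
        if isnan[0] or isnan[-1]:
            raise ValueError("trace starts or ends with missing values")
        idx = np.arange(len(v))
        v[isnan] = np.interp(idx[isnan], idx[~isnan], v[~isnan])
        return dataclasses.replace(self, values=v)


def robust_noise_sd(x: np.ndarray) -> float:
    """Robust SD via the median absolute deviation (normal-consistent)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _moving_median(v: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return v.copy()
    return signal.medfilt(v, kernel_size=w if w % 2 == 1 else w + 1)


# ---------------------------------------------------------------------------
# Oscillatory window
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowPolicy:
    """Automated surrogate for by-eye selection of the oscillatory region.

    A rolling peak-to-trough envelope (max - min of the median-smoothed
    trace over ``envelope_window`` frames) must exceed ``k`` times the
    baseline noise, estimated as the smaller robust SD of the first/last
    ``quiet_frames`` samples.  The maximal contiguous run of qualifying
    frames, at least ``min_length`` frames long, is the window.
    """

    k: float = 3.0
    envelope_window: int = 9
    quiet_frames: int = 6
    min_length: int = 5
    smooth_window: int = 3
    #: global gate: the envelope maximum must exceed ``contrast_k`` times its
    #: 10th percentile -- an oscillatory trace has quiet segments while a
    #: flat noisy trace has a uniform envelope
    contrast_k: float = 6.0


def detect_oscillatory_window(trace: Trace, policy: WindowPolicy | None = None) -> tuple[int, int]:
    """Return (start, end) sample indices (half-open) of the oscillatory
    region, or raise NonOscillatoryError."""
    policy = policy or WindowPolicy()
    v = trace.values
    n = len(v)
    if n < 10:
        raise ValueError("need at least 10 samples")
    smoothed = _moving_median(v, policy.smooth_window)
    q = min(max(policy.quiet_frames, n // 10), max(n // 3, 1))
    noise = min(robust_noise_sd(v[:q]), robust_noise_sd(v[-q:]))
    w = min(policy.envelope_window, n)
    # centred rolling range
    env = np.empty(n)
    half = w // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = smoothed[lo:hi]
        env[i] = seg.max() - seg.min()
    if policy.k > 0 and policy.contrast_k > 0:
        floor = np.percentile(env, 10)
        if env.max() <= policy.contrast_k * max(floor, 1e-12):
            raise NonOscillatoryError("no envelope contrast above baseline")
    ok = env > policy.k * noise
    # longest contiguous run
    best = (0, 0)
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    if best[1] - best[0] < policy.min_length:
        raise NonOscillatoryError("no oscillatory window found")
    return best


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakParams:
    """A single set of width / distance / prominence parameters.

    Defaults differ per arm because frame intervals differ (10-min culture
    frames give ~4-5 samples per cycle; 1.5-min embryo frames ~20).
    ``prominence_noise_k`` scales an automatic prominence floor of
    k * robust noise when ``prominence`` is None.
    """

    width: float = 1.0  # frames
    distance: int = 3  # frames
    prominence: Optional[float] = None
    prominence_noise_k: float = 3.0
    prominence_rel: float = 0.2  # fraction of the trace's signal range
    prominence_floor: float = 0.05
    smooth_window: int = 1  # moving-average pre-smoothing, frames

    @classmethod
    def culture(cls) -> "PeakParams":
        """10-min frames: ~4-5 samples per cycle, no pre-smoothing."""
        return cls(width=1.0, distance=3, smooth_window=1,
                   prominence_noise_k=3.0, prominence_rel=0.2)

    @classmethod
    def embryo(cls) -> "PeakParams":
        """1.5-min frames: ~20 samples per cycle; light smoothing keeps the
        3-point parabolic refinement well conditioned, and the width
        criterion (9 min) rejects narrow noise excursions."""
        return cls(width=6.0, distance=10, smooth_window=5,
                   prominence_noise_k=5.0, prominence_rel=0.15)


def _quiet_noise(values: np.ndarray) -> float:
    """Baseline noise from the quieter of the leading/trailing segments
    (each at least 6 frames, 10% of the trace); traces are flat before the
    first pulse and after arrest."""
    n = len(values)
    q = max(6, n // 10)
    q = min(q, max(n // 3, 1))
    return min(robust_noise_sd(values[:q]), robust_noise_sd(values[-q:]))


def _effective_prominence(values: np.ndarray, params: PeakParams) -> float:
    if params.prominence is not None:
        return params.prominence
    span = float(np.percentile(values, 98) - np.median(values))
    return max(params.prominence_noise_k * _quiet_noise(values),
               params.prominence_rel * span,
               params.prominence_floor)


def _presmooth(trace: Trace, params: PeakParams) -> Trace:
    w = int(params.smooth_window)
    if w <= 1:
        return trace
    from scipy.ndimage import uniform_filter1d
    return dataclasses.replace(
        trace, values=uniform_filter1d(trace.values, size=w, mode="nearest"))


def find_peaks(trace: Trace, params: PeakParams | None = None,
               window: tuple[int, int] | None = None) -> np.ndarray:
    """Raw peak indices (into the full trace) satisfying the parameter set."""
    params = params or PeakParams()
    lo, hi = window if window is not None else (0, len(trace))
    smoothed = _presmooth(trace, params).values
    # prominence is set from the whole trace (quiet segments included), then
    # peaks are sought inside the window
    prom = _effective_prominence(smoothed, params)
    idx, _ = signal.find_peaks(
        smoothed[lo:hi], width=params.width, distance=params.distance,
        prominence=prom,
    )
    return idx + lo


def find_troughs(trace: Trace, params: PeakParams | None = None,
                 window: tuple[int, int] | None = None) -> np.ndarray:
    """Trough indices: peaks of the negated trace with the same parameters."""
    neg = dataclasses.replace(trace, values=-trace.values)
    return find_peaks(neg, params, window)


def refine_peak_parabolic(trace: Trace, raw_index: int) -> tuple[float, float, bool]:
    """Sub-frame peak refinement by the vertex of the parabola through the
    sample at the maximum and its two neighbours.

    Returns (refined_time, refined_height, refined_flag); boundary peaks and
    flat tops are returned unrefined (flag False).
    """
    t = trace.times
    v = trace.values
    i = int(raw_index)
    if i <= 0 or i >= len(v) - 1:
        return float(t[i]), float(v[i]), False
    im, i0, ip = v[i - 1], v[i], v[i + 1]
    denom = im - 2 * i0 + ip
    if denom == 0:
        return float(t[i]), float(v[i]), False
    dt = trace.frame_interval
    delta = 0.5 * (im - ip) / denom  # in frames
    refined_time = t[i] + delta * dt
    refined_height = i0 - 0.25 * (im - ip) * delta
    return float(refined_time), float(refined_height), True


@dataclass(frozen=True)
class PeakList:
    refined_times: np.ndarray
    refined_heights: np.ndarray
    trough_times: np.ndarray
    trough_heights: np.ndarray
    raw_indices: np.ndarray
    refined_flags: np.ndarray
    params: PeakParams


def locate_peaks(trace: Trace, params: PeakParams | None = None,
                 window: tuple[int, int] | None = None) -> PeakList:
    """Detect and parabolic-refine peaks and troughs."""
    params = params or PeakParams()
    p_idx = find_peaks(trace, params, window)
    t_idx = find_troughs(trace, params, window)
    # refine on the same (possibly pre-smoothed) signal the detector saw
    trace = _presmooth(trace, params)
    neg = dataclasses.replace(trace, values=-trace.values)

    def refine_all(tr: Trace, idx: np.ndarray):
        ts, hs, fl = [], [], []
        for i in idx:
            a, b, f = refine_peak_parabolic(tr, i)
            ts.append(a)
            hs.append(b)
            fl.append(f)
        return np.array(ts), np.array(hs), np.array(fl, dtype=bool)

    pt, ph, pf = refine_all(trace, p_idx)
    tt, th, _ = refine_all(neg, t_idx)
    return PeakList(
        refined_times=pt,
        refined_heights=ph,
        trough_times=tt,
        trough_heights=-th,
        raw_indices=p_idx,
        refined_flags=pf,
        params=params,
    )


# ---------------------------------------------------------------------------
# Cycle table
# ---------------------------------------------------------------------------


@dataclass
class CycleTable:
    """Per-cell derived peak/cycle quantities."""

    cell_id: str
    n_peaks: int
    peak_times: np.ndarray  # refined, absolute minutes
    peak_heights: np.ndarray  # I+
    trough_times: np.ndarray
    trough_heights: np.ndarray  # I-
    periods: np.ndarray  # K-1 entries, minutes
    period_ratios: np.ndarray  # K-2 entries
    intensity_ratios: np.ndarray  # K-2 entries, aligned to period_ratios
    last_peak_time: float
    censored: bool = False
    condition: str = ""

    @property
    def n_ratio_pairs(self) -> int:
        return len(self.period_ratios)


def build_cycle_table(peaks: PeakList, trace: Trace, cell_id: str = "",
                      condition: str = "") -> CycleTable:
    """Derive periods, successive ratios and arrest time from refined peaks."""
    pt = np.asarray(peaks.refined_times, dtype=float)
    ph = np.asarray(peaks.refined_heights, dtype=float)
    if len(pt) < 1:
        raise ValueError("need at least one refined peak")
    periods = np.diff(pt)
    if np.any(periods <= 0):
        raise ValueError("refined peak times must be strictly increasing")
    period_ratios = periods[1:] / periods[:-1]
    # intensity ratios over the same successive-cycle pairs (K-2 entries)
    amp_ratios = ph[1:] / ph[:-1]
    intensity_ratios = amp_ratios[: max(len(pt) - 2, 0)]
    return CycleTable(
        cell_id=cell_id,
        n_peaks=len(pt),
        peak_times=pt,
        peak_heights=ph,
        trough_times=np.asarray(peaks.trough_times, dtype=float),
        trough_heights=np.asarray(peaks.trough_heights, dtype=float),
        periods=periods,
        period_ratios=period_ratios,
        intensity_ratios=intensity_ratios,
        last_peak_time=float(pt[-1]),
        condition=condition,
    )


def analyze_trace(trace: Trace, params: PeakParams | None = None,
                  use_window: bool = True,
                  window_policy: WindowPolicy | None = None,
                  cell_id: str = "", condition: str = "") -> Optional[CycleTable]:
    """Window (culture) or whole-trace (embryo) peak analysis of one trace.

    Returns None for traces with no detectable peaks (non-oscillatory).
    Missing values are interpolated when gaps are at most 2 frames.
    """
    trace = trace.interpolate_gaps()
    window = None
    if use_window:
        try:
            window = detect_oscillatory_window(trace, window_policy)
        except NonOscillatoryError:
            return None
    peaks = locate_peaks(trace, params, window)
    if len(peaks.refined_times) == 0:
        return None
    return build_cycle_table(peaks, trace, cell_id=cell_id, condition=condition)


# ---------------------------------------------------------------------------
# Censoring and alignment
# ---------------------------------------------------------------------------


def is_left_censored(trace: Trace, noise_k: float = 3.0) -> bool:
    """True when the trace begins already past its last Her1 peak: the
    first samples are the elevated maximum region and the signal only
    declines from there toward baseline."""
    v = _moving_median(trace.values, 3)
    if len(v) < 6:
        return False
    tail = v[-max(6, len(v) // 5):]
    noise = robust_noise_sd(np.diff(trace.values)) / np.sqrt(2)
    starts_high = v[0] > np.median(tail) + noise_k * max(noise, 1e-12)
    peak_at_start = int(np.argmax(v)) <= 1
    return bool(starts_high and peak_at_start)


def apply_left_censoring(tables: Sequence[CycleTable],
                         traces: dict[str, Trace],
                         acquisition_start: float) -> list[CycleTable]:
    """Set last_peak_time to the acquisition start for cells whose movie
    begins after their final peak, and mark them censored.  Censored cells
    keep their identity but must be excluded from period statistics."""
    out = []
    for tab in tables:
        tr = traces.get(tab.cell_id)
        if tr is not None and is_left_censored(tr):
            tab = dataclasses.replace(
                tab, last_peak_time=float(acquisition_start), censored=True
            )
        out.append(tab)
    return out


def align_by_first_peak(tables: Sequence[CycleTable]) -> pd.DataFrame:
    """Align all cells by their first detected peak and summarise each cycle.

    Cycle index 1 is each cell's first cycle.  Returns per-cycle median and
    25th/75th percentiles of period, I+ and I-.
    """
    rows = []
    for tab in tables:
        if tab.censored:
            continue
        for k, p in enumerate(tab.periods, start=1):
            rows.append({"cell_id": tab.cell_id, "cycle": k, "quantity": "period", "value": p})
        for k, h in enumerate(tab.peak_heights, start=1):
            rows.append({"cell_id": tab.cell_id, "cycle": k, "quantity": "Iplus", "value": h})
        for k, h in enumerate(tab.trough_heights, start=1):
            rows.append({"cell_id": tab.cell_id, "cycle": k, "quantity": "Iminus", "value": h})
    if not rows:
        raise ValueError("no uncensored cells with peaks")
    long = pd.DataFrame(rows)
    summary = (
        long.groupby(["quantity", "cycle"])["value"]
        .agg(median="median",
             q25=lambda x: float(np.percentile(x, 25)),
             q75=lambda x: float(np.percentile(x, 75)),
             n="count")
        .reset_index()
    )
    return summary


def cycle_tables_to_frame(tables: Sequence[CycleTable]) -> pd.DataFrame:
    """One row per cell: headline cycle statistics."""
    rows = []
    for t in tables:
        rows.append(
            {
                "cell_id": t.cell_id,
                "condition": t.condition,
                "n_peaks": t.n_peaks,
                "last_peak_time": t.last_peak_time,
                "n_ratio_pairs": t.n_ratio_pairs,
                "censored": t.censored,
            }
        )
    return pd.DataFrame(rows)


def ratio_pairs(tables: Sequence[CycleTable]) -> pd.DataFrame:
    """Long table of successive-cycle (period ratio, intensity ratio) pairs."""
    rows = []
    for t in tables:
        if t.censored:
            continue
        for pr, ir in zip(t.period_ratios, t.intensity_ratios):
            rows.append({"cell_id": t.cell_id, "period_ratio": pr, "intensity_ratio": ir})
    return pd.DataFrame(rows, columns=["cell_id", "period_ratio", "intensity_ratio"])
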