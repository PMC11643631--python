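"""Calibration-recovery summaries: simulate a condition cohort, run the
full trace/onset pipeline on it, and report the headline statistics that
the corresponding experiment printed (mean peaks, ratio fractions,
last-peak and onset timing)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import quantify_cohort
from .presets import get_preset
from .report import quadrant_density
from .synth import generate_cohort
from .trace import ratio_pairs

__all__ = ["CohortRecovery", "recover_condition_statistics"]


@dataclass(frozen=True)
class CohortRecovery:
    """Pipeline-recovered summary of one synthetic condition cohort."""

    condition: str
    n_cells: int
    mean_peaks: float
    sd_peaks: float
    mean_last_peak: float
    sd_last_peak: float
    n_ratio_pairs: int
    pct_period_ratio_gt1: float
    pct_intensity_ratio_gt1: float
    pct_upper_right: float
    n_onset: int
    mean_onset: float
    sd_onset: float

    def se_peaks(self) -> float:
        return self.sd_peaks / np.sqrt(max(self.n_cells, 1))

    def se_last_peak(self) -> float:
        return self.sd_last_peak / np.sqrt(max(self.n_cells, 1))

    def se_onset(self) -> float:
        return self.sd_onset / np.sqrt(max(self.n_onset, 1))

    def se_pct(self, pct: float) -> float:
        p = pct / 100.0
        return 100.0 * np.sqrt(p * (1 - p) / max(self.n_ratio_pairs, 1))


def recover_condition_statistics(preset_name: str, n: int, seed: int
                                 ) -> CohortRecovery:
    """Generate ``n`` cells from a preset and re-measure its statistics with
    the detection pipeline (window + peak finding + refinement + onset)."""
    preset = get_preset(preset_name)
    records = generate_cohort(preset, n, seed)
    tables, calls = quantify_cohort(records, preset)
    # censored cells (movie starts after the last peak) stay in last-peak
    # statistics at the acquisition start time but are excluded from
    # peak-count and cycle statistics
    with_table = [t for t in tables if t is not None]
    present = [t for t in with_table if not t.censored]
    n_peaks = np.array([t.n_peaks for t in present], dtype=float)
    last = np.array([t.last_peak_time for t in with_table], dtype=float)
    pairs = ratio_pairs(present)
    if len(pairs):
        quad, _ = quadrant_density(pairs)
        pct_slow = float((pairs["period_ratio"] >= 1).mean() * 100)
        pct_rise = float((pairs["intensity_ratio"] >= 1).mean() * 100)
        pct_ur = quad["upper_right"]
    else:
        pct_slow = pct_rise = pct_ur = float("nan")
    onsets = np.array([c.onset_time for c in calls
                       if c.onset_time is not None], dtype=float)
    return CohortRecovery(
        condition=preset_name,
        n_cells=len(present),
        mean_peaks=float(n_peaks.mean()) if len(n_peaks) else float("nan"),
        sd_peaks=float(n_peaks.std(ddof=1)) if len(n_peaks) > 1 else 0.0,
        mean_last_peak=float(last.mean()) if len(last) else float("nan"),
        sd_last_peak=float(last.std(ddof=1)) if len(last) > 1 else 0.0,
        n_ratio_pairs=int(len(pairs)),
        pct_period_ratio_gt1=pct_slow,
        pct_intensity_ratio_gt1=pct_rise,
        pct_upper_right=pct_ur,
        n_onset=int(len(onsets)),
        mean_onset=float(onsets.mean()) if len(onsets) else float("nan"),
        sd_onset=float(onsets.std(ddof=1)) if len(onsets) > 1 else 0.0,
    )
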