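"""Inclusion filtering, cohort statistics and condition comparisons.

Statistics follow the descriptive presentation of the source experiments:
sample mean ± SD (n−1 denominator), COV = SD/mean, quadrant fractions of
successive-cycle ratio pairs with boundaries at ratio = 1, and seeded
bootstrap confidence intervals for condition contrasts (no p-values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .onset import OnsetCall
from .synth import SURVIVAL_CUTOFF_MIN, CellRecord
from .trace import CycleTable, Trace, _moving_median

__all__ = [
    "inclusion_filter",
    "cov",
    "CohortStats",
    "cohort_stats",
    "quadrant_density",
    "compare_conditions",
]


# ---------------------------------------------------------------------------
# Inclusion criteria
# ---------------------------------------------------------------------------


def is_arrested(trace: Trace, table: Optional[CycleTable],
                baseline: float = 0.0) -> bool:
    """Criterion 4 operationalised: at least one detected peak followed by a
    sustained decline below half the last peak height."""
    if table is None or table.n_peaks < 1:
        return False
    v = _moving_median(trace.values, 3)
    after = v[trace.times > table.last_peak_time]
    if len(after) < 3:
        return False
    half = baseline + 0.5 * (table.peak_heights[-1] - baseline)
    below = after < half
    # sustained: the trailing run is below half-height
    return bool(below[-3:].all())


def inclusion_filter(records: Sequence[CellRecord],
                     tables: Optional[dict[str, Optional[CycleTable]]] = None
                     ) -> tuple[list[CellRecord], pd.Series]:
    """Apply the culture inclusion criteria and tally exclusions by reason.

    Criteria: (1) alive > 5 h post-dissociation; (2) one cell per field
    (violations carry a ``multi_cell`` metadata flag when present);
    (3) undivided; (4) expressed and arrested the clock reporter (checked
    against the analysed cycle table when one is supplied).
    """
    included: list[CellRecord] = []
    reasons: list[str] = []
    for rec in records:
        p = rec.program
        if p.survived_past_5h is None or p.divided is None:
            reasons.append("incomplete")
            continue
        if not p.survived_past_5h or (np.isfinite(p.survival_time)
                                      and p.survival_time <= SURVIVAL_CUTOFF_MIN):
            reasons.append("died_early")
            continue
        if getattr(p, "multi_cell", False):
            reasons.append("multi_cell")
            continue
        if p.divided:
            reasons.append("divided")
            continue
        if tables is not None:
            tab = tables.get(p.cell_id)
            if not is_arrested(rec.her1, tab):
                reasons.append("no_arrest")
                continue
        included.append(rec)
        reasons.append("included")
    tally = pd.Series(reasons, name="reason").value_counts()
    return included, tally


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------


def cov(mean: float, sd: float) -> float:
    """Coefficient of variation, SD / mean (mean must be positive)."""
    if mean <= 0:
        raise ValueError("COV requires a positive mean")
    return sd / mean


@dataclass
class CohortStats:
    n_cells: int
    mean_peaks: float
    sd_peaks: float
    cov_peaks: float
    mean_last_peak: float
    sd_last_peak: float
    quadrant_percent: dict[str, float]
    n_ratio_pairs: int
    onset_mean: float
    onset_sd: float
    onset_called_fraction: float
    censored_count: int

    def round2(self) -> "CohortStats":
        """Report-layer rounding of the COV to 2 decimals."""
        import dataclasses
        return dataclasses.replace(self, cov_peaks=round(self.cov_peaks, 2))


def quadrant_density(pairs: pd.DataFrame, grid_bins: int = 25
                     ) -> tuple[dict[str, float], np.ndarray]:
    """Quadrant percentages of (period ratio, intensity ratio) pairs.

    Boundaries at ratio = 1 on both axes; pairs exactly on a boundary are
    assigned to the '>' side.  Also returns a 2-D density grid (counts) of
    the log-ratio plane for plotting."""
    if pairs.empty:
        raise ValueError("need at least one ratio pair")
    pr = pairs["period_ratio"].to_numpy(dtype=float)
    ir = pairs["intensity_ratio"].to_numpy(dtype=float)
    slow = pr >= 1.0  # boundary counts as '>'
    rise = ir >= 1.0
    n = len(pr)
    fractions = {
        "upper_right": float(np.sum(slow & rise)) / n * 100.0,
        "upper_left": float(np.sum(~slow & rise)) / n * 100.0,
        "lower_right": float(np.sum(slow & ~rise)) / n * 100.0,
        "lower_left": float(np.sum(~slow & ~rise)) / n * 100.0,
    }
    grid, _, _ = np.histogram2d(np.log(pr), np.log(ir), bins=grid_bins)
    return fractions, grid


def cohort_stats(tables: Sequence[CycleTable],
                 onset_calls: Optional[Sequence[OnsetCall]] = None
                 ) -> CohortStats:
    """Headline statistics of an included cohort.

    Censored cells contribute to last-peak statistics (at the acquisition
    start time, per the censoring rule) but not to peak-count or ratio
    statistics."""
    if len(tables) == 0:
        raise ValueError("empty cohort")
    uncensored = [t for t in tables if not t.censored]
    n_peaks = np.array([t.n_peaks for t in uncensored], dtype=float)
    last_peaks = np.array([t.last_peak_time for t in tables], dtype=float)
    from .trace import ratio_pairs as _ratio_pairs
    pairs = _ratio_pairs(tables)
    if len(pairs):
        quad, _ = quadrant_density(pairs)
    else:
        quad = {k: np.nan for k in
                ("upper_right", "upper_left", "lower_right", "lower_left")}
    mean_peaks = float(n_peaks.mean()) if len(n_peaks) else np.nan
    sd_peaks = float(n_peaks.std(ddof=1)) if len(n_peaks) > 1 else 0.0
    if onset_calls is not None and len(onset_calls):
        onsets = np.array([c.onset_time for c in onset_calls
                           if c.onset_time is not None], dtype=float)
        called_frac = float(sum(c.clear_rise for c in onset_calls) / len(onset_calls))
        onset_mean = float(onsets.mean()) if len(onsets) else np.nan
        onset_sd = float(onsets.std(ddof=1)) if len(onsets) > 1 else 0.0
    else:
        onset_mean, onset_sd, called_frac = np.nan, np.nan, np.nan
    return CohortStats(
        n_cells=len(tables),
        mean_peaks=mean_peaks,
        sd_peaks=sd_peaks,
        cov_peaks=cov(mean_peaks, sd_peaks) if mean_peaks > 0 else np.nan,
        mean_last_peak=float(last_peaks.mean()),
        sd_last_peak=float(last_peaks.std(ddof=1)) if len(last_peaks) > 1 else 0.0,
        quadrant_percent=quad,
        n_ratio_pairs=int(len(pairs)),
        onset_mean=onset_mean,
        onset_sd=onset_sd,
        onset_called_fraction=called_frac,
        censored_count=int(sum(t.censored for t in tables)),
    )


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------


def _bootstrap_ci(a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
                  n_resamples: int) -> tuple[float, float, float]:
    """Bootstrap CI of mean(b) - mean(a)."""
    diff = float(b.mean() - a.mean())
    boots = np.empty(n_resamples)
    for i in range(n_resamples):
        ra = rng.choice(a, size=len(a), replace=True)
        rb = rng.choice(b, size=len(b), replace=True)
        boots[i] = rb.mean() - ra.mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return diff, float(lo), float(hi)


def compare_conditions(tables_a: Sequence[CycleTable],
                       tables_b: Sequence[CycleTable],
                       seed: int = 0, n_resamples: int = 2000) -> pd.DataFrame:
    """Descriptive contrast of two cohorts with seeded bootstrap 95% CIs.

    Rows: mean peaks per cell and mean last-peak time, reported as
    condition-B minus condition-A differences.  No hypothesis tests are
    emitted."""
    if len(tables_a) == 0 or len(tables_b) == 0:
        raise ValueError("both cohorts must be non-empty")
    rng = np.random.default_rng([seed])
    rows = []
    for name, getter, censor_aware in (
        ("n_peaks", lambda t: float(t.n_peaks), True),
        ("last_peak_time", lambda t: float(t.last_peak_time), False),
    ):
        a = np.array([getter(t) for t in tables_a
                      if not (censor_aware and t.censored)])
        b = np.array([getter(t) for t in tables_b
                      if not (censor_aware and t.censored)])
        diff, lo, hi = _bootstrap_ci(a, b, rng, n_resamples)
        rows.append({
            "quantity": name,
            "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
            "diff_b_minus_a": diff, "ci_lo": lo, "ci_hi": hi,
        })
    return pd.DataFrame(rows)
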