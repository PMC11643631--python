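"""Intrinsic-timer synthetic data: cell programs, rendered traces, cohorts.

The generator draws each cell's latent program directly from the observable
laws of a condition preset -- a truncated discrete peak-count distribution,
lognormal successive-ratio laws for period slowing and amplitude rise, and
a marker-onset delay coupled to the last peak -- rather than integrating a
mechanistic delayed-feedback oscillator.  Her1 traces are rendered as sums
of unimodal (truncated-Gaussian) pulses whose widths scale with the local
period; the Mesp channel is a saturating rise starting at onset.

All randomness flows from a master seed through counter-based seed
sequences (``np.random.default_rng([master, index, channel])``), so cohorts
are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .presets import ConfigurationError, GeneratorPreset
from .trace import Trace

__all__ = [
    "CellProgram",
    "CellRecord",
    "draw_cell_program",
    "render_trace",
    "generate_cohort",
    "cohort_traces_frame",
    "cohort_meta_frame",
]

log = logging.getLogger(__name__)

#: survival threshold used by the inclusion criteria, minutes
SURVIVAL_CUTOFF_MIN = 300.0


@dataclass(frozen=True)
class CellProgram:
    """Latent description of one cell: its peak schedule, arrest and onset."""

    cell_id: str
    peak_times: np.ndarray  # absolute minutes, strictly increasing
    periods: np.ndarray  # diffs of peak_times
    peak_amplitudes: np.ndarray  # a.u., > 0
    arrest_time: Optional[float]  # = last peak time; None if clock disabled
    onset_time: Optional[float]  # None when no clear marker rise
    clear_rise: bool
    condition_name: str
    survived_past_5h: bool = True
    divided: bool = False
    survival_time: float = np.inf  # minutes; traces end here if finite

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)


def _rng(seed_path: Sequence[int]) -> np.random.Generator:
    return np.random.default_rng(list(seed_path))


def draw_cell_program(preset: GeneratorPreset, rng_seed: int,
                      cell_id: str = "cell",
                      force_n_peaks: Optional[int] = None) -> CellProgram:
    """Draw one cell's program from a condition preset, deterministically
    for a given seed.

    ``force_n_peaks`` overrides the drawn peak count (used by the embryo
    flow, where peak counts vary smoothly along the axis rather than
    independently per cell); all other laws are sampled unchanged."""
    rng = _rng([rng_seed])
    if not preset.oscillation_enabled:
        clear = bool(rng.random() < preset.clear_rise_prob)
        onset = None
        if clear:
            assert preset.onset_absolute is not None
            onset = float(max(preset.onset_absolute.sample(rng), 1.0))
        return CellProgram(
            cell_id=cell_id,
            peak_times=np.empty(0),
            periods=np.empty(0),
            peak_amplitudes=np.empty(0),
            arrest_time=None,
            onset_time=onset,
            clear_rise=clear,
            condition_name=preset.condition_name,
        )

    k = int(preset.n_peaks_dist.sample(rng))
    if force_n_peaks is not None:
        if not (preset.n_peaks_dist.lo <= force_n_peaks <= preset.n_peaks_dist.hi):
            raise ConfigurationError("forced peak count outside the preset support")
        k = int(force_n_peaks)
    t1_mean = preset.effective_first_peak_mean()
    t1 = float(max(rng.normal(t1_mean, preset.first_peak_sd), 5.0))
    ratios = preset.slow_ratio_dist.sample(rng, size=max(k - 2, 0))
    periods = np.empty(max(k - 1, 0))
    if k >= 2:
        periods[0] = preset.p0
        for j, r in enumerate(ratios):
            periods[j + 1] = periods[j] * r
    peak_times = t1 + np.concatenate([[0.0], np.cumsum(periods)])
    a0 = float(max(rng.normal(preset.amp0_mean, preset.amp0_sd), 0.1))
    amp_ratios = preset.amp_ratio_dist.sample(rng, size=max(k - 1, 0))
    amplitudes = a0 * np.concatenate([[1.0], np.cumprod(amp_ratios)])
    arrest = float(peak_times[-1])
    clear = bool(rng.random() < preset.clear_rise_prob)
    onset = None
    if clear:
        delta = float(preset.onset_delay_dist.sample(rng))
        onset = max(arrest + delta, 1.0)
    return CellProgram(
        cell_id=cell_id,
        peak_times=peak_times,
        periods=periods,
        peak_amplitudes=amplitudes,
        arrest_time=arrest,
        onset_time=onset,
        clear_rise=clear,
        condition_name=preset.condition_name,
    )


def _her1_values(times: np.ndarray, program: CellProgram,
                 preset: GeneratorPreset) -> np.ndarray:
    """Noise-free Her1 signal: baseline plus truncated-Gaussian pulses at
    the program's peak times, widths tied to the local period."""
    v = np.full_like(times, preset.baseline, dtype=float)
    pts = program.peak_times
    periods = program.periods
    for i, (tau, amp) in enumerate(zip(pts, program.peak_amplitudes)):
        if len(periods) == 0:
            local = preset.p0
        elif i == 0:
            local = periods[0]
        elif i == len(pts) - 1:
            local = periods[-1]
        else:
            local = 0.5 * (periods[i - 1] + periods[i])
        sigma = preset.pulse_width_factor * local
        dt = times - tau
        pulse = amp * np.exp(-0.5 * (dt / sigma) ** 2)
        pulse[np.abs(dt) > 3.0 * sigma] = 0.0  # compact support
        v += pulse
    return v


def _mesp_values(times: np.ndarray, program: CellProgram,
                 preset: GeneratorPreset) -> np.ndarray:
    v = np.full_like(times, preset.mesp_baseline, dtype=float)
    if program.onset_time is not None:
        rel = np.clip(times - program.onset_time, 0.0, None)
        v += preset.mesp_amplitude * np.tanh(rel / preset.mesp_rise_tau)
    return v


def render_trace(program: CellProgram, preset: GeneratorPreset,
                 rng_seed: int) -> tuple[Trace, Trace]:
    """Render the Her1 and Mesp channels of one cell on the preset's
    imaging grid.  Deterministic given the seed."""
    if len(program.periods) > 0:
        shortest = float(program.periods.min())
        if preset.frame_interval >= shortest / 2:
            log.warning(
                "frame interval %.1f min >= half the shortest period %.1f min: "
                "oscillations of cell %s may alias",
                preset.frame_interval, shortest, program.cell_id,
            )
    end = preset.duration
    if np.isfinite(program.survival_time):
        end = min(end, program.survival_time)
    n = int(np.floor((end - preset.imaging_start_offset) / preset.frame_interval)) + 1
    n = max(n, 2)
    times = preset.imaging_start_offset + preset.frame_interval * np.arange(n)

    her1_clean = _her1_values(times, program, preset)
    mesp_clean = _mesp_values(times, program, preset)
    rng_h = _rng([rng_seed, 0])
    rng_m = _rng([rng_seed, 1])
    her1 = her1_clean + rng_h.normal(0.0, preset.noise_sd, size=n)
    mesp = mesp_clean + rng_m.normal(0.0, preset.noise_sd, size=n)
    kw = dict(frame_interval=preset.frame_interval,
              t0_offset=preset.imaging_start_offset)
    return (Trace(times=times, values=her1, **kw),
            Trace(times=times, values=mesp, **kw))


@dataclass(frozen=True)
class CellRecord:
    program: CellProgram
    her1: Trace
    mesp: Trace


def generate_cohort(preset: GeneratorPreset, n: int, seed: int,
                    died_frac: float = 0.0,
                    divided_frac: float = 0.0) -> list[CellRecord]:
    """Generate ``n`` independent cells with reproducible per-cell seeds.

    ``died_frac`` / ``divided_frac`` plant cells that fail the culture
    inclusion criteria (death before 5 h, or division) so downstream
    filtering can be exercised; both default to 0 (a post-inclusion cohort).
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not (0 <= died_frac <= 1 and 0 <= divided_frac <= 1 and
            died_frac + divided_frac <= 1):
        raise ConfigurationError("invalid exclusion fractions")
    fate_rng = _rng([seed, 10**6])
    records: list[CellRecord] = []
    for i in range(n):
        cell_seed_path = [seed, i]
        program = draw_cell_program_from_path(preset, cell_seed_path,
                                              cell_id=f"{preset.condition_name}_{i:04d}")
        u = fate_rng.random()
        if u < died_frac:
            survival = float(fate_rng.uniform(60.0, SURVIVAL_CUTOFF_MIN - 1))
            program = _with_fate(program, survived=False, divided=False,
                                 survival=survival)
        elif u < died_frac + divided_frac:
            program = _with_fate(program, survived=True, divided=True)
        her1, mesp = render_trace_from_path(program, preset, cell_seed_path)
        records.append(CellRecord(program=program, her1=her1, mesp=mesp))
    return records


def _with_fate(p: CellProgram, survived: bool, divided: bool,
               survival: float = np.inf) -> CellProgram:
    import dataclasses
    return dataclasses.replace(p, survived_past_5h=survived, divided=divided,
                               survival_time=survival)


def draw_cell_program_from_path(preset: GeneratorPreset,
                                seed_path: Sequence[int],
                                cell_id: str = "cell") -> CellProgram:
    """Counter-based variant: the seed is a path of integers."""
    # reuse draw_cell_program logic with a composed deterministic seed
    rng = _rng(seed_path)
    derived = int(rng.integers(0, 2**31 - 1))
    return draw_cell_program(preset, derived, cell_id=cell_id)


def render_trace_from_path(program: CellProgram, preset: GeneratorPreset,
                           seed_path: Sequence[int]) -> tuple[Trace, Trace]:
    rng = _rng(list(seed_path) + [1])
    derived = int(rng.integers(0, 2**31 - 1))
    return render_trace(program, preset, derived)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def cohort_traces_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Long per-frame table: cell_id, frame, t_min, her1, mesp."""
    frames = []
    for rec in records:
        n = len(rec.her1)
        frames.append(pd.DataFrame({
            "cell_id": rec.program.cell_id,
            "frame": np.arange(n),
            "t_min": rec.her1.times,
            "her1": rec.her1.values,
            "mesp": rec.mesp.values,
        }))
    return pd.concat(frames, ignore_index=True)


def cohort_meta_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Per-cell ground-truth metadata table."""
    rows = []
    for rec in records:
        p = rec.program
        rows.append({
            "cell_id": p.cell_id,
            "condition": p.condition_name,
            "n_peaks_true": p.n_peaks,
            "arrest_time_true": p.arrest_time if p.arrest_time is not None else np.nan,
            "onset_time_true": p.onset_time if p.onset_time is not None else np.nan,
            "clear_rise_true": p.clear_rise,
            "survived_past_5h": p.survived_past_5h,
            "divided": p.divided,
            "survival_time": p.survival_time,
        })
    return pd.DataFrame(rows)
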