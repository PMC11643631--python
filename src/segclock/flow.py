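"""Embryo-like anterior-ward cell flow along a reference curve.

Each simulated cell exits the tailbud (TB) at a drawn time; exit starts its
intrinsic clock program.  The reference curve is anchored at the posterior
tail tip, which extends away from the tissue at ``advection_speed``: in
that frame a cell advects anteriorly at constant speed after exit, while in
the laboratory frame it simply stays where it left the TB.  Because the
tail extends, later-exiting cells sit more posteriorly on the final axis
and arrest later, which yields the graded arrest pattern: somites are
assigned by arc-length bins (width = somite length) of the lab-frame
position, and within a somite rostral (anterior) cells arrest before
caudal ones.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from pydantic import BaseModel, ConfigDict, Field

from .kymo import ReferenceCurve
from .presets import GeneratorPreset, NormalSpec
from .synth import _her1_values, _mesp_values, draw_cell_program

__all__ = ["EmbryoFlowConfig", "generate_embryo_flow"]


class EmbryoFlowConfig(BaseModel):
    """Geometry and kinematics of the synthetic embryo arm."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    n_cells: int = Field(gt=0, default=64)
    advection_speed: float = Field(ge=0.0, default=1.0)  # um / min anterior-ward
    tb_exit_times: NormalSpec = NormalSpec(mean=60.0, sd=30.0)
    somite_length: float = Field(gt=0.0, default=50.0)  # um
    frame_interval: float = Field(gt=0.0, default=1.5)  # min
    duration: float = Field(gt=0.0, default=450.0)  # movie minutes
    start_arc: float = 30.0  # um: arc length where cells join the PSM
    lateral_jitter: float = 2.0  # um
    #: jitter (in quantile units) of the exit-rank -> peak-count coupling;
    #: small values make peak counts vary smoothly along the axis so cells
    #: within one somite differ by at most ~1 peak
    peak_count_coherence_sd: float = Field(ge=0.0, default=0.03)


def generate_embryo_flow(cfg: EmbryoFlowConfig, preset: GeneratorPreset,
                         curve: ReferenceCurve, seed: int
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a tracked cohort flowing anteriorly past the curve.

    Returns (track table, per-cell table).  Track columns: cell_id, frame,
    t_min, x, y, z, her1, mesp.  Cell columns: cell_id, tb_exit_time,
    n_peaks_true, arrest_time_true, onset_time_true, somite,
    arc_at_arrest.  Times are movie minutes; the clock program starts at TB
    exit.  Frames are half-open [0, n_frames).
    """
    n_frames = int(np.floor(cfg.duration / cfg.frame_interval)) + 1
    frame_ids = sorted(curve.frames)
    t_grid = cfg.frame_interval * np.arange(n_frames)

    # per-cell generators and exit times first: peak counts follow the
    # empirical exit rank (plus a little jitter) through the preset's
    # quantile function, then unit-step clamping along the exit order, so
    # counts vary smoothly along the axis (somite neighbours differ by at
    # most one peak) while the cohort marginal stays close to the
    # calibrated distribution
    cell_rngs = [np.random.default_rng([seed, i]) for i in range(cfg.n_cells)]
    exits = np.array([float(max(cfg.tb_exit_times.sample(r), 0.0))
                      for r in cell_rngs])
    forced_ks: list[Optional[int]] = [None] * cfg.n_cells
    if preset.oscillation_enabled:
        cdf = np.cumsum(preset.n_peaks_dist.pmf())
        support = preset.n_peaks_dist.support()
        n = cfg.n_cells
        ranks = stats.rankdata(exits, method="ordinal")
        lo, hi = int(support[0]), int(support[-1])
        ks = np.empty(n, dtype=int)
        for i in range(n):
            u = ranks[i] / (n + 1.0)
            if cfg.peak_count_coherence_sd > 0:
                u += cell_rngs[i].normal(0.0, cfg.peak_count_coherence_sd)
            u = float(np.clip(u, 1e-9, 1 - 1e-9))
            ks[i] = int(support[int(np.searchsorted(cdf, u))])
        order = np.argsort(exits, kind="stable")
        for a, b in zip(order[:-1], order[1:]):
            ks[b] = int(np.clip(ks[b], max(ks[a] - 1, lo), min(ks[a] + 1, hi)))
        forced_ks = [int(k) for k in ks]

    track_rows = []
    cell_rows = []
    for i in range(cfg.n_cells):
        cell_rng = cell_rngs[i]
        exit_t = float(exits[i])
        prog_seed = int(cell_rng.integers(0, 2**31 - 1))
        cid = f"emb_{i:04d}"
        program = draw_cell_program(preset, prog_seed, cell_id=cid,
                                    force_n_peaks=forced_ks[i])
        # the intrinsic timer starts at TB exit: shift program to movie time
        program = dataclasses.replace(
            program,
            peak_times=program.peak_times + exit_t,
            arrest_time=(program.arrest_time + exit_t
                         if program.arrest_time is not None else None),
            onset_time=(program.onset_time + exit_t
                        if program.onset_time is not None else None),
        )
        # tip-anchored arc: the cell recedes anteriorly from the extending tip
        arcs = cfg.start_arc + cfg.advection_speed * np.clip(t_grid - exit_t, 0.0, None)
        # lab-frame axis position (0 = tail tip at the end of the movie):
        # fixed at exit; later exits are more posterior
        lab_pos = cfg.start_arc + cfg.advection_speed * (cfg.duration - exit_t)
        her1 = _her1_values(t_grid, program, preset)
        mesp = _mesp_values(t_grid, program, preset)
        if preset.noise_sd > 0:
            her1 = her1 + cell_rng.normal(0.0, preset.noise_sd, size=n_frames)
            mesp = mesp + cell_rng.normal(0.0, preset.noise_sd, size=n_frames)
        arrest = program.arrest_time
        if arrest is not None:
            arc_at_arrest = lab_pos
            somite = int(np.floor(lab_pos / cfg.somite_length))
        else:
            arc_at_arrest, somite = np.nan, -1
        for f in range(n_frames):
            cf = frame_ids[min(f, len(frame_ids) - 1)]
            xy = curve.point_at_arc(cf, arcs[f])
            jitter = (cell_rng.normal(0.0, cfg.lateral_jitter, size=2)
                      if cfg.lateral_jitter > 0 else np.zeros(2))
            track_rows.append((cid, f, t_grid[f], xy[0] + jitter[0],
                               xy[1] + jitter[1], 0.0, her1[f], mesp[f],
                               somite))
        cell_rows.append({
            "cell_id": cid,
            "tb_exit_time": exit_t,
            "n_peaks_true": program.n_peaks,
            "arrest_time_true": arrest if arrest is not None else np.nan,
            "onset_time_true": (program.onset_time
                                if program.onset_time is not None else np.nan),
            "somite": somite,
            "arc_at_arrest": arc_at_arrest,
        })
    tracks = pd.DataFrame(
        track_rows,
        columns=["cell_id", "frame", "t_min", "x", "y", "z", "her1", "mesp",
                 "somite"],
    )
    return tracks, pd.DataFrame(cell_rows)
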