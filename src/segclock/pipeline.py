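"""End-to-end orchestration: simulate -> segment -> trace -> onset -> kymo
-> report, with a validated config, reproducible seeds and CSV outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .flow import EmbryoFlowConfig, generate_embryo_flow
from .kymo import ReferenceCurve, build_event_kymograph
from .onset import OnsetCall, detect_onset
from .presets import GeneratorPreset, get_preset
from .report import CohortStats, cohort_stats, inclusion_filter
from .synth import (CellRecord, cohort_meta_frame, cohort_traces_frame,
                    generate_cohort)
from .trace import (CycleTable, PeakParams, analyze_trace,
                    apply_left_censoring, cycle_tables_to_frame, ratio_pairs)

__all__ = ["PipelineConfig", "quantify_cohort", "run_pipeline"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "trace", "onset", "kymo", "report")


class PipelineConfig(BaseModel):
    """Validated configuration of a full synthetic run."""

    model_config = ConfigDict(frozen=True)

    preset: str = "culture_psm4"
    n_cells: int = Field(gt=0, default=50)
    seed: int = 0
    outdir: str = "segclock_out"
    stages: tuple[str, ...] = ALL_STAGES
    died_frac: float = Field(ge=0.0, le=1.0, default=0.0)
    divided_frac: float = Field(ge=0.0, le=1.0, default=0.0)
    embryo_n_cells: int = Field(gt=0, default=48)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def quantify_cohort(records: Sequence[CellRecord], preset: GeneratorPreset,
                    peak_params: Optional[PeakParams] = None,
                    censor: bool = True
                    ) -> tuple[list[Optional[CycleTable]], list[OnsetCall]]:
    """Run the trace-analysis and onset stages over a generated cohort.

    The culture arm analyses peaks inside the detected oscillatory window;
    the embryo arm uses the whole trace with a single parameter set.
    Returns per-cell cycle tables (None for non-oscillating cells) and
    onset calls, in cohort order."""
    if peak_params is None:
        peak_params = (PeakParams.embryo() if preset.arm == "embryo"
                       else PeakParams.culture())
    use_window = preset.arm != "embryo"
    tables: list[Optional[CycleTable]] = []
    calls: list[OnsetCall] = []
    for rec in records:
        tab = analyze_trace(rec.her1, peak_params, use_window=use_window,
                            cell_id=rec.program.cell_id,
                            condition=rec.program.condition_name)
        tables.append(tab)
        calls.append(detect_onset(rec.mesp))
    if censor:
        present = [t for t in tables if t is not None]
        traces = {rec.program.cell_id: rec.her1 for rec in records}
        censored = apply_left_censoring(present, traces,
                                        acquisition_start=preset.imaging_start_offset)
        by_id = {t.cell_id: t for t in censored}
        tables = [by_id.get(t.cell_id) if t is not None else None for t in tables]
    return tables, calls


def _stats_payload(stats: CohortStats) -> dict:
    import dataclasses
    d = dataclasses.asdict(stats.round2())
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; write CSVs, a manifest and logs.

    Returns a result bundle (paths and headline statistics).  A stage
    failure aborts with a stage-tagged error; outputs of completed stages
    are preserved on disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = get_preset(config.preset)
    bundle: dict = {"outdir": str(outdir)}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "preset": json.loads(preset.model_dump_json()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    records = tables = calls = None
    for stage in config.stages:
        try:
            if stage == "simulate":
                records = generate_cohort(preset, config.n_cells, config.seed,
                                          died_frac=config.died_frac,
                                          divided_frac=config.divided_frac)
                cohort_traces_frame(records).to_csv(outdir / "traces.csv", index=False)
                cohort_meta_frame(records).to_csv(outdir / "cells.csv", index=False)
                bundle["traces_csv"] = str(outdir / "traces.csv")
            elif stage == "trace":
                records = _require(records, "trace", "simulate")
                included, tally = inclusion_filter(records)
                tables, calls = quantify_cohort(included, preset)
                present = [t for t in tables if t is not None]
                cycle_tables_to_frame(present).to_csv(outdir / "cycles.csv", index=False)
                ratio_pairs(present).to_csv(outdir / "ratio_pairs.csv", index=False)
                tally.to_csv(outdir / "inclusion_tally.csv")
                bundle["cycles_csv"] = str(outdir / "cycles.csv")
                bundle["included"] = included
            elif stage == "onset":
                calls = _require(calls, "onset", "trace")
                included = bundle["included"]
                rows = []
                for rec, call, tab in zip(included, calls, tables):
                    delta = (call.onset_time - tab.last_peak_time
                             if call.onset_time is not None and tab is not None
                             else np.nan)
                    rows.append({"cell_id": rec.program.cell_id,
                                 "onset_min": call.onset_time,
                                 "clear_rise": call.clear_rise,
                                 "delta_vs_last_peak": delta})
                pd.DataFrame(rows).to_csv(outdir / "onsets.csv", index=False)
            elif stage == "kymo":
                curve = ReferenceCurve.static_line(500.0, frames=[0])
                flow_cfg = EmbryoFlowConfig(n_cells=config.embryo_n_cells)
                emb_preset = get_preset("embryo_psm4")
                tracks, cells = generate_embryo_flow(flow_cfg, emb_preset,
                                                     curve, config.seed)
                events = cells.dropna(subset=["arrest_time_true"]).rename(
                    columns={"arrest_time_true": "event_time",
                             "arc_at_arrest": "aligned_arc"})
                kym = build_event_kymograph(events, bin_width=10.0)
                tracks.to_csv(outdir / "embryo_tracks.csv", index=False)
                pd.DataFrame(kym.values).to_csv(outdir / "kymograph.csv",
                                                index=False)
                bundle["kymograph"] = kym
            elif stage == "report":
                tables = _require(tables, "report", "trace")
                present = [t for t in tables if t is not None]
                stats = cohort_stats(present, calls)
                payload = _stats_payload(stats)
                (outdir / "report.json").write_text(json.dumps(payload, indent=2))
                bundle["stats"] = stats
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return bundle


def _require(value, stage: str, dependency: str):
    if value is None:
        raise ValueError(f"stage {stage!r} requires stage {dependency!r} first")
    return value
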