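#!/usr/bin/env python
"""Embryo-arm kymograph and intra-somite phase profile.

Simulates an anterior-ward cell flow past a reference curve (the timer of
each cell starts at its tailbud exit), projects the tracked cells onto the
curve, builds last-peak and onset event kymographs, and measures the
rostro-caudal phase profile within each somite (rank correlation of
position vs arrest time).
"""

import json
from pathlib import Path

import pandas as pd

from segclock import get_preset
from segclock.flow import EmbryoFlowConfig, generate_embryo_flow
from segclock.kymo import (ReferenceCurve, build_event_kymograph,
                           somite_phase_profile)

SEED = 20270


def main() -> None:
    outdir = Path("results/kymograph")
    outdir.mkdir(parents=True, exist_ok=True)
    preset = get_preset("embryo_psm4")
    curve = ReferenceCurve.static_line(700.0, frames=[0], curvature=30.0)
    cfg = EmbryoFlowConfig(n_cells=96, advection_speed=1.0,
                           somite_length=50.0)
    tracks, cells = generate_embryo_flow(cfg, preset, curve, SEED)
    scratch = Path("scratch")
    scratch.mkdir(exist_ok=True)
    tracks.to_csv(scratch / "embryo_tracks.csv", index=False)  # bulky per-frame table
    cells.to_csv(outdir / "cells.csv", index=False)

    events = {}
    for label, col in (("last_peak", "arrest_time_true"),
                       ("onset", "onset_time_true")):
        ev = cells.dropna(subset=[col]).rename(
            columns={col: "event_time", "arc_at_arrest": "aligned_arc"})
        kym = build_event_kymograph(ev, bin_width=10.0, color_semantics=label)
        pd.DataFrame(kym.values).to_csv(outdir / f"kymograph_{label}.csv",
                                        index=False)
        events[label] = {"n_cells": kym.total_cells,
                         "n_bins": int(kym.values.shape[1])}
        print(f"{label} kymograph: {kym.total_cells} events over "
              f"{kym.values.shape[0]} rows x {kym.values.shape[1]} bins")

    labelled = cells.dropna(subset=["arrest_time_true"]).rename(
        columns={"arc_at_arrest": "arc_length",
                 "arrest_time_true": "event_time"})
    profile, rho, n_exc = somite_phase_profile(labelled)
    profile.to_csv(outdir / "phase_profile.csv", index=False)
    print(f"intra-somite phase profile: Spearman rho = {rho:.2f} "
          f"(caudal cells arrest later), {n_exc} unlabelled cells excluded")
    (outdir / "summary.json").write_text(json.dumps(
        {"events": events, "phase_rho": round(rho, 3),
         "n_somites": int(labelled['somite'].nunique())}, indent=2))


if __name__ == "__main__":
    main()
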