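#!/usr/bin/env python
"""Differentiation-marker onset relative to clock arrest.

Calls Mesp signal-onset in the culture-control, embryo and clock-disabled
cohorts and relates it to the last Her1 peak: the onset-arrest delay
distribution, the fraction of onsets after arrest, and the onset timing of
her1-/-;her7-/- cells, which is computed without any peak detection.
"""

import json
from pathlib import Path

import numpy as np

from segclock import generate_cohort, get_preset, quantify_cohort
from segclock.onset import detect_onset, onset_delay_summary

SEED = 20250


def main() -> None:
    outdir = Path("results")
    outdir.mkdir(exist_ok=True)
    summary = {}

    for name, n in [("culture_psm4_control", 60), ("embryo_psm4", 128)]:
        preset = get_preset(name)
        records = generate_cohort(preset, n, SEED)
        tables, calls = quantify_cohort(records, preset)
        paired = [(t, c) for t, c in zip(tables, calls) if t is not None]
        delays = onset_delay_summary(*zip(*paired))
        d = delays["delta_min"].dropna()
        summary[name] = {
            "n_cells": n,
            "n_delays": int(len(d)),
            "mean_delta_min": round(float(d.mean()), 1),
            "pct_onset_after_arrest": round(float((d > 0).mean() * 100), 1),
            "n_no_onset": int(delays["no_onset"].sum()),
        }
        s = summary[name]
        print(f"{name}: onset - arrest = {s['mean_delta_min']} min "
              f"({s['pct_onset_after_arrest']}% after the last peak, "
              f"{s['n_no_onset']} cells without onset)")

    mutant = get_preset("culture_her1her7")
    records = generate_cohort(mutant, 60, SEED + 1)
    onsets = np.array([c.onset_time for c in
                       (detect_onset(r.mesp) for r in records)
                       if c.onset_time is not None])
    summary["culture_her1her7"] = {
        "n_cells": 60,
        "n_onsets": int(len(onsets)),
        "mean_onset_min": round(float(onsets.mean()), 1),
        "sd_onset_min": round(float(onsets.std(ddof=1)), 1),
    }
    s = summary["culture_her1her7"]
    print(f"her1-/-;her7-/-: onset {s['mean_onset_min']} +/- "
          f"{s['sd_onset_min']} min across {s['n_onsets']} cells "
          f"(no peaks detected anywhere)")
    (outdir / "onset_vs_arrest.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
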