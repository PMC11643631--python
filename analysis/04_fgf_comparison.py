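#!/usr/bin/env python
"""FGF extension of the intrinsic timer: treated vs control wells.

Compares the FGF-treated (n=54) and control (n=44) culture cohorts the way
the split-pool experiment was analysed: mean peak number and mean last-peak
time with seeded bootstrap confidence intervals, plus the quadrant split of
successive-cycle ratios under FGF.
"""

import json
from pathlib import Path

from segclock import compare_conditions, generate_cohort, get_preset, quantify_cohort
from segclock.recovery import recover_condition_statistics

SEED = 20260


def main() -> None:
    outdir = Path("results")
    outdir.mkdir(exist_ok=True)
    control_p = get_preset("culture_psm4_control")
    fgf_p = get_preset("culture_psm4_fgf")
    tab_c, _ = quantify_cohort(generate_cohort(control_p, 44, SEED), control_p)
    tab_f, _ = quantify_cohort(generate_cohort(fgf_p, 54, SEED + 1), fgf_p)
    report = compare_conditions([t for t in tab_c if t],
                                [t for t in tab_f if t], seed=SEED)
    report.to_csv(outdir / "fgf_comparison.csv", index=False)
    for _, row in report.iterrows():
        print(f"{row['quantity']}: control {row['mean_a']:.2f} +/- "
              f"{row['sd_a']:.2f} vs FGF {row['mean_b']:.2f} +/- "
              f"{row['sd_b']:.2f}; difference {row['diff_b_minus_a']:.2f} "
              f"[95% CI {row['ci_lo']:.2f}, {row['ci_hi']:.2f}]")

    fgf = recover_condition_statistics("culture_psm4_fgf", 54, SEED + 1)
    quad = {
        "pct_period_slowing": round(fgf.pct_period_ratio_gt1, 1),
        "pct_intensity_rise": round(fgf.pct_intensity_ratio_gt1, 1),
        "pct_slow_and_rise": round(fgf.pct_upper_right, 1),
        "n_ratio_pairs": fgf.n_ratio_pairs,
    }
    print(f"FGF cycle pairs (n={quad['n_ratio_pairs']}): "
          f"{quad['pct_period_slowing']}% slow, "
          f"{quad['pct_intensity_rise']}% rise, "
          f"{quad['pct_slow_and_rise']}% both")
    (outdir / "fgf_quadrants.json").write_text(json.dumps(quad, indent=2))


if __name__ == "__main__":
    main()
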