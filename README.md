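# segclock

Single-cell analysis of the vertebrate segmentation clock's intrinsic
timer: simulation of transient Her1 oscillations and Mesp differentiation
onset, brightfield single-cell segmentation, oscillation peak/cycle
quantification, and somite kymograph construction.

## The scientific problem

During somitogenesis, the segmentation clock is visible as kinematic waves
of *her1* expression travelling anteriorly through the presomitic mesoderm
(PSM) and arresting at each forming somite. Isolated zebrafish PSM cells
reproduce the core of this program cell-autonomously: their Her1-YFP
oscillations slow (period ratio of successive cycles
p<sub>n+1</sub>/p<sub>n</sub> &gt; 1), rise in peak intensity
(I<sup>+</sup><sub>n+1</sub>/I<sup>+</sup><sub>n</sub> &gt; 1), and arrest
after a small number of peaks, with onset of the differentiation marker
Mesp-ba-mKate2 temporally coupled to the last peak. An intrinsic timer
started at tailbud exit runs down as cells flow anteriorly; exogenous FGF
lengthens it.

This package is for quantitative biologists who want to analyse such
single-cell reporter movies — or to test an analysis chain end-to-end
without imaging data. It provides:

- **`segclock.synth` / `segclock.presets`** — an intrinsic-timer generator.
  Each cell draws a peak count K from a discretised truncated normal,
  periods compounding as p_{k+1} = r_k · p_k with lognormal r_k
  (parameterised by P(r &gt; 1)), amplitudes likewise, and a marker onset at
  arrest + Δ. Condition presets (culture PSM2/3/4, tailbud, ±FGF, embryo
  PSM4, *her1⁻ᐟ⁻;her7⁻ᐟ⁻*) are calibrated to published cohort statistics.
- **`segclock.scenes` / `segclock.segmentation`** — synthetic brightfield
  movies with ground-truth masks, and the segmentation chain: adaptive
  histogram equalisation → guided filter → morphological gradient (disk
  radius 2) → Otsu → central blob → Chan-Vese active contour (300
  iterations, smooth factor 1, contraction bias 0.1), with per-frame QC
  flags instead of manual curation.
- **`segclock.trace`** — oscillatory-window detection, `find_peaks`-based
  peak/trough detection with a single width/distance/prominence parameter
  set per arm, sub-frame parabolic refinement (vertex of the parabola
  through a maximum and its two neighbours), cycle tables, successive-cycle
  ratios, left censoring, first-peak alignment.
- **`segclock.onset`** — clear-rise classification and sustained-threshold
  Mesp onset calling (also from a fixed-ROI maximum, for the clock-disabled
  arm).
- **`segclock.flow` / `segclock.kymo`** — anterior-ward cell flow past a
  reference curve (timer starts at tailbud exit), nearest-point projection
  with arc-length coordinates, event kymographs, intra-somite phase
  profiles.
- **`segclock.report`** — inclusion filtering, cohort statistics
  (mean ± SD, COV = SD/mean), quadrant densities of
  (period ratio, intensity ratio) pairs, bootstrap condition contrasts.

## Worked example

```python
from segclock import generate_cohort, get_preset, quantify_cohort, cohort_stats

preset = get_preset("culture_psm4")          # posterior-quarter PSM cells
records = generate_cohort(preset, 174, seed=1)
tables, onset_calls = quantify_cohort(records, preset)
stats = cohort_stats([t for t in tables if t is not None], onset_calls)
print(f"{stats.mean_peaks:.1f} +/- {stats.sd_peaks:.1f} peaks, "
      f"COV {stats.cov_peaks:.2f}; upper-right quadrant "
      f"{stats.quadrant_percent['upper_right']:.0f}%")
```

prints

```
4.3 +/- 1.6 peaks, COV 0.37; upper-right quadrant 57%
```

i.e. this simulated 174-cell culture cohort oscillated 4.3 times on
average before arrest (coefficient of variation 0.37), and 57% of
successive cycle pairs both slowed and rose in peak intensity — the
signature of the cell-autonomous timer running down. The same surface is
available from the shell:

```sh
segclock report --preset culture_psm4 --n-cells 12 --seed 3 --outdir out/
# n=12 cells, 4.58 +/- 1.62 peaks (COV 0.35); last peak 333 +/- 109 min
```

The numbered drivers under `analysis/` run the full study arms
(simulation, trace quantification, onset-vs-arrest timing, FGF contrast,
embryo kymograph, segmentation benchmark) and write their tables under
`results/`:

```sh
python analysis/02_trace_quantification.py
# culture_psm4: 4.7 +/- 1.59 peaks (COV 0.34), 471 cycle pairs: 80.3% slow, ...
# embryo_psm4: 3.39 +/- 0.91 peaks (COV 0.27), 181 cycle pairs: 80.1% slow, ...
```

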