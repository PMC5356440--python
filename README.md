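# mtcortex

Quantitative image-analysis tools for studying how microtubules and their
regulators engage the epithelial cell cortex. During apico-basal epithelial
differentiation, minus-end anchoring proteins (e.g. ninein) relocate from
the centrosome to junction-associated non-centrosomal microtubule
organizing centres, a redeployment driven by plus-end tracking proteins
(CLIP-170), cortical receptors (IQGAP1) and active Rac1. The measurements
that quantify this biology are implemented here as a tested, reusable
library:

- **Junction intensity profiles** — fluorescence read along the normal to a
  traced cell–cell junction (21 readings over 2 µm by default), baselined
  against background; per-profile peaks are normalized to the control group
  to report a relative intensity and a percent reduction.
- **Cortical targeting metrics** — the percentage of microtubules
  approaching the cortex at perpendicular angles (45–90° to the junction
  tangent) per 10 × 10 µm cortical box; cortical contacts per 10 µm of
  junction; and a structure-tensor (nematic) analysis of image texture
  giving the dominant fibril orientation θ and an anisotropy score in
  [0, 1], reported as an acute angle to the junction.
- **Comet detection** — plus-end comet segmentation by background
  subtraction, thresholding and a closed particle-area gate
  (0.2–1.2 µm²) applied identically across a comparison group, with counts
  per 10 × 10 µm box.
- **Comet dynamics post-analysis** — tracks are split where consecutive
  segment orientations differ by more than 30°, classified into growth and
  pause events by a speed-threshold run-length rule, and summarized per
  cell (mean growth speed in µm/min, growth length, percent of events
  growing/pausing). Speeds are binned into four equal groups over
  [0, v_max] with v_max = mean + 1 SD of the fastest cell.
- **Group statistics** — a decision tree that screens each group with the
  D'Agostino–Pearson normality test and routes to t-test / one-way ANOVA
  (normal) or Mann–Whitney U / Kruskal–Wallis with Dunn's
  multiple-comparison post-test (otherwise); plus organoid bud-count
  distributions (0/1/2/3/4+ buds per organoid).
- **Synthetic scenes** (`mtcortex.synthetic`) — seeded generators for
  junction mosaics, enriched cortical puncta, filament fields with a
  von Mises approach-angle distribution, elliptical comet fields and
  two-state (growth ↔ pause) Markov trajectories, each with complete
  ground truth, so every stage above is validated by parameter recovery.

## Worked example

Measure a 50% loss of junctional signal from synthetic scenes
(`examples/02_junction_profiles.py`):

```sh
$ python examples/02_junction_profiles.py
profiles: 201 control, 201 treated
mean peak: control 163.2, treated 96.4
ratio 0.591 -> 40.9% reduction (ground truth: 50%)
```

Two arms share the same junction geometry; the treated arm's junctional
punctum density is halved. About 200 profiles per arm recover the halved
enrichment as a measured peak reduction of 40–50% for typical seeds.

Comet dynamics (`examples/05_track_dynamics.py`) recovers a simulated
12 µm/min growth speed and shows the speed-group shift when growth slows:

```sh
$ python examples/05_track_dynamics.py
     treatment  mean_growth_speed_um_min  mean_growth_length_um  pct_events_pausing
       control                     11.62                   3.14               69.62
rac1_inhibited                      5.79                   1.69               67.15

vmax = 13.1 µm/min (fastest cell mean + 1 SD); speed-group shares (%):
  control: very slow 0, slow 1, fast 7, very fast 92
  rac1_inhibited: very slow 3, slow 77, fast 20, very fast 0
```

The remaining examples cover scene synthesis, targeting metrics, comet
detection and the statistics decision tree; each prints the numbers it
computes and a line on what they mean.

A thin CLI wraps the same functions (`mtcortex simulate|profiles|targeting|
comets|tracks|stats|run-all`); `mtcortex run-all --config
examples/demo_config.yaml --out <dir>` runs the full synthetic →
measurements → statistics pipeline from one declarative config, writing
CSVs, a log and a run-metadata file that echoes every threshold and seed.

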