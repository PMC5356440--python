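# Methods

This note documents the models, conventions and numerical choices behind
mtcortex, and what its synthetic validation does and does not establish.

## Coordinates, calibration and angles

All continuous positions are in µm with the origin at the field's top-left
corner, x rightward and y downward (image convention). Pixel (row, col)
covers `[col·p, (col+1)·p) × [row·p, (row+1)·p)` at pixel size `p` µm/px,
so pixel centres sit at half-integer multiples of `p`. The default
calibration is 0.1 µm/px, which maps the 0.2–1.2 µm² comet gate to 20–120
pixels exactly.

Orientations of undirected structures (junctions, fibrils) live on
[0°, 180°); differences between segment *directions* are folded to
[0°, 180°]; approach angles between a filament and a junction tangent are
acute, on [0°, 90°]. A filament trace is ordered distal → proximal: its
last vertex is the cortex-proximal end, and approach direction is averaged
over the final 1 µm because cortical approach is a local property of the
tip, not of the whole trace.

## Junction profiles

Profiles are taken at `n_positions` evenly spaced arc lengths
`s_i = (i + ½)L/n` (interior placement keeps the tangent well defined),
sampled bilinearly along the local normal: `n_samples` readings spanning
`span` µm symmetrically about the junction — 21 readings over 2 µm
(0.1 µm spacing) by default, with the junction at the centre sample
(index 10). Background is subtracted and negatives clipped to zero, since
intensities are physical; the default background is the image's 5th
percentile (robust for sparse bright structures under fixed exposure), and
an explicit ROI mean can be supplied instead. Baselining at background 0
is idempotent, and scaling the image by k scales peaks by k while leaving
ratios and percent reductions unchanged.

The primary statistic is the per-profile peak (maximum sample); the
point-wise mean profile and its SD are returned for plotting. Group
comparison reports `ratio = mean(treated peaks)/mean(control peaks)` and
`100·(1 − ratio)` percent reduction, plus control-normalized per-profile
peaks for significance testing. Profiles whose samples leave the image are
skipped with a warning; tables keep path, position and sample identifiers
so the caller can choose the unit of replication (profile, junction or
cell).

## Cortical targeting

A filament is scored in a cortical box (10 × 10 µm by default, left/top
edges inclusive) if its proximal end lies inside; the perpendicular band
is the *closed* range 45–90°, so a filament at exactly 45° counts as
perpendicular. A filament contacts the junction when its proximal endpoint
is within `d_contact` of the junction polyline (default 0.25 µm, ~2–3
pixels at default calibration; the geometric notion of "contact" is a
package choice and configurable). Contacts are normalized per 10 µm of
junction length. Both metrics are rotation-equivariant by construction.

The image-level orientation analysis computes per-pixel gradients by
centred finite differences after light Gaussian pre-smoothing (σ = 1 px),
averages the gradient second-moment (nematic) tensor over the ROI, and
reports the fibril axis — the eigenvector of the smaller eigenvalue,
perpendicular to the dominant gradient direction — with anisotropy
`(λ₁ − λ₂)/(λ₁ + λ₂)` ∈ [0, 1]. A region whose total gradient energy falls
below a floor (10⁻⁸ of the squared dynamic range) has no defined
orientation; this is flagged, not raised, because constant regions are
legitimate inputs.

## Comet detection

Default background estimation is a 5 µm rolling-median filter (robust to
the sparse bright comets themselves); the default threshold is Otsu on the
background-subtracted image. Both are explicit, recorded choices —
alternative constants can be passed, and the pipeline configuration
applies a single parameter set to every image of a comparison group.
Connected components use 8-connectivity; the area gate is inclusive at
both ends. Saturated or blank images produce an empty detection list with
a logged warning.

## Track dynamics

Linking per-frame detections is deliberately simple plumbing: greedy
mutual-nearest association in order of increasing distance, with a
distance budget proportional to frames elapsed and a configurable gap
tolerance. It is validated only on low-density synthetic fields and is not
a substitute tracker for dense or crossing-heavy data.

The post-tracking analysis is the scientific content. Tracks are split
wherever consecutive segment orientations differ by strictly more than
30°; zero-length segments inherit the last defined orientation and never
trigger a split. Growth/pause classification uses a speed-threshold
run-length rule: segments slower than `pause_speed_max` (default
1.5 µm/min) form pause events when at least `min_pause_frames` (default 2)
run consecutively; everything else is growth. Events tile the track.
Because events alternate by construction, the *fraction of events* pausing
is pinned near one half and carries no stationary interpretation; the
*fraction of time* pausing is the quantity with a Markov stationary
expectation `p_gp/(p_gp + p_pg)` and is emitted alongside the event-count
convention. Per-treatment numbers are means of per-cell means — the cell
is the unit of replication.

Speed groups: the fastest cell is the cell with the highest mean growth
speed across all treatments; `v_max` is that cell's mean plus one sample
SD; four equal-width bins partition [0, v_max], the last bin right-closed,
with faster speeds folded into the top bin. Capping at v_max preserves
resolution at low-to-medium speeds.

## Statistics decision tree

Each group is screened with the D'Agostino–Pearson omnibus test, which is
undefined below n = 8; smaller groups route directly to the nonparametric
branch (the "too small for normality analysis" case made precise). If all
groups pass at α = 0.05, two groups get an unpaired two-sided t-test and
more get one-way ANOVA; otherwise Mann–Whitney U or Kruskal–Wallis with
Dunn's post-test. Dunn's test uses the pooled-rank z statistic with tie
correction `Σ(t³ − t)/(12(N − 1))` and Bonferroni adjustment over all
pairs (the classic form; the adjustment is recorded in the output). It is
implemented in-package and cross-checked against a permutation null in the
test suite. The full decision trace — every normality p-value and the
chosen branch — is attached to each result.

Bud distributions report the percentage of organoids with 0/1/2/3/4+ buds
per region, then average regions within genotype × day; a genotype × day
two-way ANOVA on region percentages is available as an optional analysis.

## Synthetic data: what it emulates and what it does not

The generators define the validation conditions:

- **Cell mosaic** — a Voronoi partition of the field (seeds mirrored
  across the borders so all cells are finite); internal edges stand in for
  adherens-junction traces. Real junctions are curved and irregular; the
  mosaic tests geometry handling, not segmentation.
- **Junction scenes** — ridges with Gaussian cross-section plus constant
  background and additive Gaussian noise floored at zero. The ridge
  truncates at 6σ (truncation error < 2·10⁻⁸ of the amplitude).
- **Cortical puncta** — homogeneous Poisson background plus Poisson
  puncta along junctions at linear density `junction_density ×
  enrichment_factor`, displaced normally with SD `band_width/2`. The
  default junctional density of 6 /µm makes the junctional band
  quasi-continuous at the PSF scale, as junctional protein bands appear in
  fixed images; the enrichment factor is the ground-truth dial the profile
  analysis recovers.
- **Filament fields** — straight filaments anchored on junctions; the
  approach angle is `target ± δ/2` with δ ~ von Mises(0, κ), folded to
  [0°, 90°]; κ = 0 is exactly uniform on [0°, 90°] and large κ pins the
  target. Real microtubules curve; straight filaments isolate the angular
  scoring from trace quality.
- **Comet fields** — per-frame counts Poisson(density × area/100 µm²);
  uniform-intensity ellipses with analytic area uniform in the requested
  range, random axis ratio (1.3–2.2) and orientation. Centres stay one
  maximal spot radius inside the field so every truth record is fully
  rendered; an optional hard-core separation constructs scenes whose spots
  are individually resolvable (the count stays Poisson). Detection
  precision/recall claims hold for such separated scenes at SNR ≥ 5;
  overlapping comets merge and are not resolved — no claim is made there.
- **Trajectories** — two-state Markov chains started in growth; growth
  advances along a persistent direction by Normal(v, v_sd)·Δt, pause is
  isotropic jitter of SD 0.01 µm (localization error). Defaults:
  2 s frame interval, 40 frames, 12 µm/min growth. Neither acquisition
  interval nor pause kinetics are universal; both are explicit parameters.

Passing parameter-recovery tests on these scenes shows the measurement
code is correct under its stated model; it does not certify performance on
real micrographs with structured background, uneven illumination or
segmentation error.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: ~200 profiles per arm and
3 seeds for enrichment recovery (ratios 1.0/0.5/0.25, tolerance ±10
percentage points at ratio 0.5 plus monotonicity); 1000 uniform-angle
filaments for perpendicular scoring (50% ± 3 binomial SE); stripe images
at 10°/37°/80° (recovery within 1°, anisotropy ≥ 0.9, isotropic-noise
anisotropy < 0.05); 3 constructed comet scenes at 5 per 100 µm², SNR 5,
2 µm separation (precision and recall ≥ 0.95 at 0.3 µm matching); 1000
random tracks against brute-force splitting/classification references; 500
simulated trajectories × 3 seeds for dynamics recovery (speed within 5%,
pause-time fraction within ±0.1 of stationary); and 2000 null simulations
at n = 20 for the routed test's empirical size (0.05 ± 0.01).

## Known limitations

No filament or junction segmentation from images (traces are inputs); no
sub-pixel spot fitting; the linker is not a multi-hypothesis tracker; no
3D reconstruction; no effect-size machinery beyond percent change. The
event/time denominator ambiguity in pause quantification and the pause
rule's constants are surfaced as configuration rather than fixed
behaviour.
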