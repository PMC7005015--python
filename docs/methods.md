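# Methods

This note documents the models, conventions and design choices behind
`dyadgaze`, in the order data flows through the pipeline.

## Coordinate and timing conventions

Scene pixels are 0-based, origin top-left, x rightward, y downward.
Timestamps are float64 milliseconds; at the 60 Hz sampling rate
consecutive samples are exactly 1000/60 ms apart. Integer milliseconds
were rejected because they cannot represent the 16.67 ms sample period
without drift. Gaze time t maps to scene frame `floor(t · 24 / 1000)`
(the recorder runs gaze at 60 Hz against 24 fps video; no join rule is
standard, so this floor rule is fixed here). Degrees are obtained from
pixels by the per-axis linear scale of the scene camera (60°/1280 px,
46°/960 px); a trigonometric camera model is deliberately not used, since
the dispersion threshold itself presupposes a fixed deg/px scale.

## Fixation detection (I-DT)

Classic dispersion-threshold identification: the window is initialised
to the minimum duration (50 ms), accepted if its dispersion is within
threshold (0.5°), then grown sample by sample until the threshold would
break; the centroid is the arithmetic mean of member samples. Dispersion
is the **larger side of the window's bounding box in degrees**
(`dispersion_metric="max"`); the alternative range-sum convention
(`"sum"`) is available because vendor definitions differ and the one
behind the default extraction settings is not published. A single
invalid sample terminates any open window — loss periods are excluded
from valid time rather than interpolated, so no gap-bridging is
attempted. Valid time is the count of valid samples times the sample
period. A timing tolerance of 1e-6 ms is applied when testing whether a
window spans the minimum duration, so that timestamps accumulated in
floating point cannot drop an exactly-50 ms window.

## Face geometry

The face is a convex quadrilateral (vertices ordered TL, TR, BR, BL).
Between detections it is propagated through index-matched point
correspondences by a least-squares **similarity** transform (4 dof:
translation, rotation, isotropic scale) — enough to follow head-motion
induced box movement and robust at 15 points; a full affine fit is a
config switch. Propagation is refused (`RedetectSignal`) below 15
correspondences or from 150 frames after the last detection, mirroring a
semi-automatic workflow in which a human confirms each fresh detection;
the confirmation GUI itself is replaced by this signal contract.

Classification: a point is inside the box edge-inclusively; the
upper/lower split is the segment joining the midpoints of the left and
right edges, with points exactly on the midline assigned **upper**. Both
tie-breaks are arbitrary but fixed. Fixations are classified at their
midpoint frame's box; when that frame has no box, the nearest box within
`box_gap_tolerance_frames` (default 6, i.e. 0.25 s) is used, beyond
which the fixation is unclassifiable and counts as data loss. The
6-frame default is this package's own choice; no published rule exists
for fixations spanning tracking gaps.

## Speech coding

Annotations are explicit event streams (`speech_on`, `speech_off`,
`interruption`, `resume_second_sentence`); the second-sentence resume
point is an annotation token, never inferred from audio. Coding per
speaker: cap total coded speech at 30 s per task; an interruption after
≥ 20 s of coded speech ends the period at the interruption; an earlier
interruption discards the insufficient first segment and codes a single
second segment from the resume token (at most two segments ever). The
wearer's own speech codes the *speaking* condition, the partner's the
*listening* condition; when both are silent, no condition is coded.

## ROI outcomes and statistics

Fixations are intersected with coded periods, durations clipped at
period boundaries (clipping preserves additivity). Per cell
(participant × task × speech state): `face_prop` = (upper + lower) /
(upper + lower + outside) fixation time; `upper_prop` = upper / face
time, undefined when face time is zero. Cells with no valid fixation
time are flagged and dropped listwise from the ANOVA (a classical mixed
ANOVA needs complete within-subject data; no imputation).

The 2×2×2 mixed ANOVA (Group between; Speech, Task within) is computed
stratum by stratum from per-subject contrast scores; in balanced designs
this is algebraically identical to the classical cell-means
decomposition (verified against a hand sums-of-squares oracle), and with
unequal groups it yields Type-III tests, matching the df = N − 2
reporting convention. All within factors have two levels, so sphericity
holds trivially and no correction is applied. Partial η² =
SS_effect / (SS_effect + SS_error-of-that-stratum).

Nonparametric follow-ups use exact enumeration where feasible (Wilcoxon
signed-rank for ≤ 25 untied pairs; Mann-Whitney U for group sizes ≤ 10
untied), otherwise the normal approximation with tie correction. Effect
sizes follow r = Z/√N with N the number of observations entering the
test (2 × pairs for signed-rank; n₁ + n₂ for U). Spearman correlations
get exact p by full rank-permutation enumeration for n ≤ 8 untied pairs,
else the t approximation. Group trait comparisons are pooled-variance t
tests with Cohen's d (pooled SD); Welch is a flag away.

## Density maps and permutation inference

The face template is 110 × 140 px at 0.1°/px (11° × 14°); the original
work's template resolution is unknown, so this convention is the
package's own. The quadrilateral-to-template map anchors the four box
vertices to the template corners and inverts the bilinear interpolation
(a quadratic in one barycentric coordinate; for parallelogram boxes it
degenerates to the affine case — consistent with describing the remap as
linear transformations). Each on-face fixation deposits its duration at
its remapped centroid pixel (`deposit_mode="fixation"`; per-sample
deposition is a config switch).

Smoothing is an isotropic Gaussian with **σ = 2°** (20 px); since
"width" is ambiguous, an FWHM = 2° interpretation is available via
`kernel_width_is_fwhm`. At the template boundary the truncated kernel is
renormalized per source pixel (the input is divided by the blurred
all-ones mask before filtering), which conserves total mass exactly.
Maps are then normalized to unit mass per participant so participants
with more face time do not dominate the group statistics; whether the
original analysis normalized per participant is unstated, and this
choice is documented rather than inherited.

Inference: pooled-variance two-sample t per pixel (df = n₁ + n₂ − 2);
zero-variance pixels get t = 0 when means agree and a ±∞ sentinel
otherwise. Clusters are connected components (8-neighbor by default,
4 available) of pixels beyond the two-sided critical value at the
cluster-forming p = 0.01, signed, with **cluster size in pixels** as the
statistic (cluster mass is intentionally not offered). The null
exchanges whole-participant labels preserving group sizes; each
iteration records the maximum cluster size with signs pooled
(|t| thresholding) — the signed-vs-pooled choice is unstated in the
cluster-permutation literature's application here, and pooled maxima are
the more conservative two-sided option. p = (b + 1)/(m + 1) avoids
exact-zero p-values; significance at p < 0.05 family-wise. An exhaustive
mode enumerates all group splits for small designs and is used as an
oracle cross-check.

## Synthetic cohorts

The generator emulates the recording situation, not its pixels: no video
frames are rendered.

* **Face track** — a base 11° × 14° quadrilateral centred in the
  1280 × 960 scene undergoes a smooth per-frame similarity transform
  (low-pass-filtered random walks in translation up to the configured
  amplitude, with proportionally small rotation and scale). Point
  correspondences are exact images of 30 face-anchored points; a dropout
  schedule exercises the 15-point re-detection rule.
* **Gaze** — alternating fixation/saccade segments, because the I-DT
  detector assumes piecewise-stationary gaze: fixation targets are drawn
  from a mixture of Gaussian components in template coordinates
  (eyes/nasion/mouth) plus an off-face fraction; positions follow the
  moving face box with 0.02° jitter; saccades are 1–3 sample ballistic
  jumps. Fixation durations are normal (mean 300 ms, SD 120 ms,
  floor 80 ms) — literature-plausible placeholders, since the study the
  defaults emulate reports no saccade or duration statistics.
* **Loss** — a two-state Markov chain (mean invalid run 6 samples,
  ≈ 100 ms) with stationary invalid fraction equal to `loss_rate`
  (default 0.08, between the two groups' reported loss means):
  contiguous runs model smiling/occlusion episodes, not i.i.d. drops.
* **Speech** — alternating speaker turns (mean 14 s) filling the
  session; sessions default to 60 s per task so that each speech state
  accrues roughly the 30 s the cropping rule would keep.
* **Traits** — AQ and LSAS from group-specific normals truncated to
  instrument ranges (group A: AQ 14.0 ± 6.28, LSAS 36.45 ± 16.32;
  group B: AQ 21.59 ± 8.65, LSAS 48.19 ± 21.07 — in the range of
  published cross-cultural adult samples, with group B the higher-trait
  group). `trait_coupling` routes a per-participant
  latent gaze tendency into both the off-face weight and the scores, so
  the correlation stage has a recoverable signal.
* **Effects** — `InjectedEffect` adds a mixture component (default
  weight 0.25, σ 1°, mouth position (5.5°, 9.8°)) to group B only;
  state-specific profiles (e.g. off-face 0.45 speaking vs 0.15
  listening, chosen to land in the ballpark of the reported median face
  proportions) create the speaking/listening gap.

What passing tests on these data do **not** show: robustness to
non-similarity face deformation (expression, out-of-plane rotation),
correlated gaze–head dynamics, imperfect point tracking (correspondences
here are exact), annotation errors, or non-Gaussian spatial gaze
structure. The generator is a contract fixture, not a simulator of any
particular participant population.

## Verification studies and problem sizes

`dyadgaze.studies` holds the package's own calibration experiments, all
seeded: family-wise error over 200 null cohorts of 14 + 14 maps
(120 fixations per map, 500 permutation iterations — enough for a 0.05
decision via the (b+1)/(m+1) estimator); detector contracts on a stream
of 17–500 ms stationary segments repeated 100 times; end-to-end recovery
over 50 replicates with 30 s sessions (14/group for the cluster study,
25/group for the ANOVA power study). Session lengths and iteration
counts in these studies are chosen to keep each study in the minutes
range on a single core while leaving decision margins wide; the
full-size defaults (60 s sessions, 10,000 iterations) remain the
package defaults.

## Known limitations

* The ANOVA assumes complete cells after listwise deletion; no
  mixed-effects alternative is provided.
* Listening is coded strictly as the partner's speech; mutual silence
  belongs to neither condition.
* The pipeline consumes face quadrilaterals and point correspondences;
  face detection and optical flow on real video are out of scope.
* Proprietary eye-tracker binary formats are not read; tables are
  delimited text.
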