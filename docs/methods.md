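# Methods

This note documents the models, conventions, parameter defaults, and
design decisions behind `welfaremetrics`, and what the synthetic test
suite does and does not demonstrate.

## Scope and coordinate conventions

The package starts where the neural stack ends. Upstream models (object
detection, pose estimation, instance segmentation, multi-object tracking,
embedding encoders, snapshot scorers) are treated as replaceable producers
of typed records; everything downstream of them — feature algebra,
geometry, scoring rules, identification logic — lives here and is what
the tests exercise.

Image coordinates follow the universal convention: origin at the top-left
pixel, x rightward, y downward. World (pen) coordinates are centimeters
with the origin at the pen corner bound to the first configured corner
point, length (580 cm default) along x and width (380 cm default) along
y. Frame rates are carried as stream metadata: 20 fps for cattle corridor
clips, 15 fps for pig pens.

The 16-slot cattle skeleton requires 11 named keypoints (head, withers,
pin, four elbows, four hooves); the remaining five slots are free and can
be bound to any upstream naming via an alias map at read time. The exact
ordering used by any particular annotation scheme is deliberately not
hard-coded: the alias map is the binding mechanism.

## Cattle locomotion features

Per frame, with `L = ‖withers − pin‖` (pixels):

| feature | definition | units |
|---|---|---|
| body length | `L` | px |
| right/left step | `abs(x(front hoof) − x(back hoof)) / L` | – |
| hoof–elbow shift (×4) | `s · (x(elbow) − x(hoof)) / L` | – |
| head position | `(ȳ(hooves) − y(head)) / mean leg height` | – |
| back straightness | `exp(−RMS⊥ / (λ·L))` | [0, 1] |

`s ∈ {+1, −1}` is the walking direction, inferred from the net withers
x-displacement over the clip, so left-to-right and right-to-left passes
produce identical features. Step sizes are horizontal rather than
Euclidean distances because the corridor is imaged side-on and gait reads
along the direction of travel. Head position is referenced to the hoof
ground line and normalized by the mean vertical hoof-to-elbow extent
(one concrete reading of a height normalizer "by the average height of
hooves and elbows"; an alternative — the mean y of all eight points —
differs only by a constant factor for a rigid skeleton). Keypoints below
a confidence floor (default 0.3) mark the features depending on them as
missing (NaN) rather than fabricating values.

**Back straightness.** The back-silhouette edge (≥ 5 ordered points,
supplied by an upstream segmenter) is fitted with its total-least-squares
line; the RMS of *perpendicular* residuals, normalized by body length, is
mapped through `exp(−rms/(λL))`. This mapping is the package's choice:
the defining constraints are only the endpoints (collinear → 1, deep arch
→ 0) and monotonicity in arch depth; the exponential satisfies both, is
smooth, and is invariant to rigid motion and uniform scaling by
construction. λ (default 0.05) sets how fast the score falls: an arch
with sagitta 10 % of body length has RMS⊥ ≈ 0.0298 L (parabolic arc) and
scores ≈ 0.55.

## Locomotion-score classification

The 8 normalized features (everything except body length, which is a
normalizer only) form a per-frame signal. Missing frames are linearly
interpolated across gaps of at most 3 frames; longer gaps split the clip,
so no gait is fabricated across occlusions. Rolling windows (default 20
frames = 1 s at 20 fps, stride 5; both configurable since no canonical
values exist) are scored by a pluggable classifier; a clip's score is the
unrounded arithmetic mean of its window scores.

The reference window scorer is deliberately simple and desk-scale: each
window is pooled into per-channel summary statistics (mean, std, min,
max, mean |Δ|) and classified by gradient-boosted trees
(`HistGradientBoostingClassifier`, 150 iterations, seeded). The scorer
emits a continuous value — the probability-weighted mean of the five
classes — so the clip mean is well defined; `predict_class` gives the
discrete label where accuracy is the metric. A recurrent network trained
on real clips can be dropped in behind the same interface; nothing in the
pipeline depends on the scorer's internals. Trees were preferred over a
linear model because the pooled feature set mixes a few highly
informative channels (e.g. the window mean of back straightness) with
many noisy ones, a regime where axis-aligned splits are markedly more
sample-efficient than a regularized linear boundary.

## Open-set markerless identification

Each known animal's anchor is the coordinate-wise mean ("center of mass")
of its embedding points (3-D by default). Queries go to the Euclidean-
nearest anchor; if even the nearest is farther than the rejection
threshold the query is rejected, signaling a poor acquisition or an
unknown animal. Ties resolve to the lexicographically smallest id,
making assignment deterministic. Enrollment is retraining-free: new ids
add anchors, repeated ids update running means (counts are stored to keep
the mean exact).

The rejection threshold is a required configuration value — there is no
universal number, since it lives in the units of whatever encoder is
plugged in. For a labeled training set, `derive_threshold` computes the
99th percentile of within-cluster anchor distances, **capped at half the
minimum inter-anchor distance**. The cap matters: by the triangle
inequality, any query within `thr ≤ sep/2` of its own anchor is at least
as close to it as to any other anchor, so every accepted in-cluster query
is correctly assigned — without the cap, a ~3.4σ percentile radius
against 3σ cluster midpoints admits a ≈ 0.1 % per-query confusion rate
even at 6σ separation.

## Pig pen analytics

**Geometry.** The pixel→cm map is the projective transform fitted to the
four configured pen corners (4-point direct linear solution, via
scikit-image). Corner correspondence is exact to < 10⁻⁶ cm and the
transform is validated for invertibility; mapped track points falling
more than 20 cm outside the pen rectangle are flagged.

**Activity.** Posture budgets are frame counts divided by fps, so
standing + lying always equals tracked duration exactly. Distance sums
Euclidean world-frame steps where *both* endpoint frames are standing;
steps implying speed above 300 cm/s (a generous bound for a pig) are
dropped as tracker glitches and tallied for diagnostics rather than
silently inflating distance.

**Occlusion recovery.** A per-identity history of world coordinates is
kept; when an id disappears and a new id appears within 50 cm (default)
of the lost id's last position within 30 frames (2 s), the new id is
relabeled to the lost one, with simultaneous candidates resolved greedily
by smallest distance. This repairs the common tracker failure where pigs
emerging from an occlusion get fresh (or swapped) ids.

**Interactions.** Contact is bbox intersection over the *smaller* box's
area (threshold 0.10): the min-area denominator lets a small animal's
head inside a large animal's box register, which intersection-over-union
would dilute. Contact is confirmed as an interaction by movement
evidence, OR-combined: either centroid moved > 2 cm since the previous
frame, either posture changed, or the structural similarity (SSIM, 7×7
Gaussian-weighted windows) between consecutive grayscale crops of the
union bbox fell below 0.90. Without frame images the SSIM term is
skipped and logged. The fine label is the maximal-IoU cross pair of part
polygons above 0.02: mouth–tail, mouth–ear, mouth–body, head-to-head
(mouth/ear vs mouth/ear), any other overlapping pair → generic body
contact; the label is symmetric in the participants and the actor is
recorded when the mouth belongs to exactly one animal. Consecutive
confirmed frames of a pair merge into an event; gaps up to 1 s are
bridged (durations are reported downstream, so some merging rule is
required; 1 s is conservative at 15 fps). Enrichment contact is polygon
overlap; the ball additionally counts displacement > 3 cm. All
thresholds are configuration with the defaults above — none has a
canonical published value. Frontal vs. central head contacts are not
distinguished; the part-IoU rule cannot separate them.

**Reports.** Interaction minutes are attributed frame-by-frame to
wall-clock hour bins for each participant, so totals are conserved across
bins exactly.

## Color identification

Mean RGB over the detected tag/mark region → CIE L\*a\*b\* assuming sRGB
encoding and D65 white (no camera profile is published with the data;
the conversion is configurable) → CIEDE2000 against the per-pen roster.
The CIEDE2000 implementation is the full formulation (G chroma
correction, S_L/S_C/S_H weights, R_T hue-rotation term) and is verified
against the standard 34-pair published verification set to 4 decimal
places, and against an independent library implementation on random
pairs. In mark mode the upstream symbol class (triangle/circle/line/
cross) filters the candidate set before color matching; this module
consumes the symbol label, it does not classify shapes. Matches with
ΔE00 above 25 (deliberately loose default) are rejected as unidentified.

## Synthetic fixtures: what they emulate, and what they don't

The generators produce *detector outputs*, not images (except schematic
SSIM crops): their purpose is controllable ground truth, not realism.

- **Gait clips**: sinusoidal leg kinematics with diagonal phasing, walked
  at 3 px/frame, 20 fps. Lameness level ℓ ∈ 1..5 drives three signatures
  jointly: the front-right swing amplitude shrinks by 12 % per level
  (step asymmetry), head-bob amplitude grows 3 px per level, and back
  sagitta grows 5 % of body length per level (level 1 is flat, scoring
  ≈ 1). Gaussian pixel noise (default studies use σ = 1 px) perturbs all
  coordinates. Real lame gait is not sinusoidal and its signatures are
  correlated with confounds (surface, speed, motivation); passing the
  recovery tests shows the *pipeline* preserves and decodes the encoded
  ordinal signal, not that the classifier transfers to field video.
- **Embedding clusters**: isotropic Gaussians with exact minimum
  centroid separation; the identity encoder stands in for the coat-
  pattern network. Tests at 6σ separation characterize the assignment
  rule, not any real encoder's geometry.
- **Pen scenes**: pigs rest at ≥ 72 cm-spaced home positions (580 × 380
  cm pen, 15 fps); scripted events teleport a pig into contact
  (overlapping boxes, ≥ 2.6 cm/frame in-contact oscillation so motion
  confirmation fires every frame, part polygons realizing the intended
  label), onto a fixture, into a lying interval, or along a straight
  walk of known length. Teleport steps exceed the 300 cm/s gate and are
  dropped from distance by design. SSIM crops are textured rectangles on
  a flat background — sufficient because only *relative* similarity
  change is consumed. Noise-free scripts are recovered exactly; field
  trackers add jitter, fragmentation, and missed detections the scripts
  do not model.
- **Tag colors**: Gaussian L\*a\*b\* perturbations around roster
  templates (the default 12-template roster keeps ≥ 15 ΔE00 mutual
  separation). Accuracy decays monotonically as σ grows — mirroring the
  real failure mode of nearby tag colors confusing the matcher.

## Numerical choices and degenerate inputs

- Homography corner residuals above 10⁻⁶ cm raise; three collinear
  corners raise before estimation.
- Zero body length (withers = pin) and zero-area bounding boxes are
  errors, not NaNs.
- Back edges are orientation-normalized by sorting on x; fewer than 5
  points raise.
- Exact distance/ΔE ties in identification resolve to the smallest id;
  part-IoU ties resolve in sorted part-name order. Both make outputs
  order-independent and reproducible.
- Every stochastic component (generators, classifier) takes an explicit
  seed; identical seeds reproduce identical outputs bit-for-bit.
- Problem sizes in the test and acceptance suites (100 random
  quadrilaterals, 200 training windows from 40 clips, 50 evaluation
  clips of 60 frames, 10⁴ color draws, 6-pig 40 s scenes) are the
  package's chosen study conditions: large enough to exercise each
  property meaningfully, small enough to complete in seconds on one CPU
  core.

## Known limitations

- The window scorer is a stand-in for a sequence model trained on real
  annotated clips; its synthetic accuracy says nothing about field
  accuracy.
- Occlusion recovery assumes the re-emitted track appears near the lost
  position; long occlusions with large displacement defeat it, as does a
  tracker that swaps ids without dropping them (no re-identification is
  attempted beyond coordinate history).
- Interaction confirmation is motion-based; two animals resting in
  sustained contact are deliberately not counted as interacting.
- The color pipeline assumes sRGB/D65; uncalibrated cameras shift L\*a\*b\*
  coordinates and effectively shrink template separation.
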