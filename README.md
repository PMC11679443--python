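# welfaremetrics

Analytic core for camera-based livestock welfare monitoring. The package
consumes the outputs of an upstream detection/tracking stack — pose
keypoints, bounding-box tracks, segmentation polygons, color regions —
and turns them into welfare metrics for two barn scenarios:

- **Dairy cattle health monitoring** (side + top-down corridor cameras):
  per-frame locomotion features from a 16-keypoint pose, a back-straightness
  score from the segmented back-silhouette edge, rolling-window locomotion
  scoring on the 1 (normal) – 5 (severely lame) scale, and open-set
  markerless identification over a pluggable coat-pattern embedding.
- **Pig pen behavioral analysis** (one dome camera per pen): perspective
  mapping of pixel tracks to pen centimeters, posture time budgets and
  standing-travel distance, identity recovery after occlusions, rule-based
  detection of animal–animal and animal–enrichment interactions, and pig
  identification from ear-tag / livestock-mark color via CIEDE2000.

No video decoding and no neural inference happen here: detectors, pose
estimators, segmenters and trackers are upstream, and their interfaces
(the encoder for identification, the snapshot scorer for body condition)
are pluggable callables. A seeded synthetic-fixture module generates every
input format with controllable ground truth, so the whole pipeline is
testable on a laptop.

## The quantities computed

**Locomotion features** (per frame, from the 16-keypoint side-view pose):
body length `L = ‖withers − pin‖`; right/left step size
`|x(front hoof) − x(back hoof)| / L`; four hoof–elbow shifts
`± (x(elbow) − x(hoof)) / L` (sign normalized by walking direction); head
position `(ȳ_hooves − y_head) / mean leg height`; and back straightness
`exp(−RMS⊥ / (λ L))`, where `RMS⊥` is the root-mean-square perpendicular
residual of the back edge about its total-least-squares line (1 = straight
back, 0 = severe arching; λ = 0.05 by default). All normalized features
are invariant to translation and uniform scaling of the image.

**Locomotion score**: the 8 normalized features are cut into rolling
windows (default 20 frames, stride 5); a pluggable sequence classifier
maps each window to a score in [1, 5] (reference implementation:
gradient-boosted trees over pooled window statistics, emitting the
probability-weighted class mean); the clip score is the arithmetic mean
of its window scores.

**Open-set identification**: anchor(id) = center of mass of that animal's
embedding points; a query is assigned to the Euclidean-nearest anchor if
within a rejection threshold, else rejected (new animal or bad
acquisition). Enrollment adds anchors or updates running means — no
retraining.

**Pen analytics**: a 4-corner projective transform maps pixels to the
580 × 380 cm pen; distance sums Euclidean steps between consecutive
*standing* frames (steps implying > 300 cm/s are dropped as tracker
glitches); bbox contact uses intersection over the *smaller* box (≥ 0.10),
confirmed by motion > 2 cm, posture change, or SSIM < 0.90 between
consecutive union-bbox crops; the fine label is the maximal-IoU body-part
pair (mouth–tail, mouth–ear, mouth–body, head-to-head, body contact).

**Color identification**: mean region RGB → CIE L\*a\*b\* (sRGB, D65) →
CIEDE2000 against the pen roster, with optional mark-symbol filtering and
open-set rejection (default ΔE00 > 25).

## Worked example

```bash
welfaremetrics synth gait --out poses.jsonl --edges-out edges.jsonl --level 3 --seed 4
welfaremetrics cattle-ls --poses poses.jsonl --back-edges edges.jsonl --out features.csv
# wrote 120 feature rows (21 windows) to features.csv
head -2 features.csv
```

```
frame_index,body_length,right_step,left_step,head_position,fr_shift,fl_shift,br_shift,bl_shift,back_straightness
0,203.30620675074124,0.8304556466193281,0.7316089450989101,3.014170057851941,0.004277552357474525,0.001512289165617531,0.002780461067302046,0.004785540210259091,0.5177553687714224
```

The clip is a synthetic level-3 walker: 120 frames at 20 fps with 1 px
keypoint noise. Body length ≈ 203 px; the right step (0.83) outpaces the
left (0.73) because the generator shortens the lame leg's swing; the back
score ≈ 0.52 reflects the level-3 back arch (a straight back scores 1.0).
The 21 rolling windows are what a trained classifier scores and averages
into the clip's locomotion score.

```bash
welfaremetrics synth pen --out pen --seed 4
welfaremetrics pig-report --tracks pen/tracks.jsonl --pen pen/pen.yaml --out report
# 1 events, 4 animals -> report/
cat report/interactions.csv
```

```
start,end,kind,participants,fine_label,actor
90,135,animal_animal,0|1,mouth_to_tail,0
```

The scripted mouth-to-tail contact between pigs 0 and 1 (frames 90–135,
3 s at 15 fps) is recovered with its exact span, label, and actor;
`report/report.csv` holds per-pig standing/lying seconds and distance, and
`report/hourly.csv` the interaction minutes per pig per hour bin.

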