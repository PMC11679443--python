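"""Cattle locomotion features and window-based locomotion scoring.

A side-view pose (16 keypoints) yields per-frame gait features: step sizes,
hoof–elbow shifts and head height, normalized to be invariant to camera
distance and animal position, plus a back-straightness score computed from
the segmented back-silhouette edge.  Feature sequences are cut into rolling
windows and scored by a pluggable sequence classifier on the 1 (normal) to
5 (severely lame) locomotion scale; a clip's score is the mean over its
windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier

from .errors import (
    DegeneratePoseError,
    DegenerateTrainingError,
    InsufficientEdgeError,
    SchemaError,
)
from .types import CattlePose, GaitFeatureVector

logger = logging.getLogger(__name__)

#: Minimum keypoint confidence for a keypoint to contribute to features.
DEFAULT_CONFIDENCE_FLOOR = 0.3

#: Decay length of the back-straightness mapping, as a fraction of body
#: length: score = exp(-rms_residual / (LAMBDA * body_length)).
DEFAULT_BACK_LAMBDA = 0.05

DEFAULT_WINDOW = 20  # frames (1 s at the 20 fps side camera)
DEFAULT_STRIDE = 5
DEFAULT_MAX_GAP = 3  # frames of missing features bridged by interpolation


@dataclass(frozen=True)
class BackEdge:
    """Ordered points along the back-silhouette contour edge.

    Orientation is normalized so that x is non-decreasing (points are
    sorted along x); ``body_length_ref`` is the withers–pin distance in the
    same pixel frame and sets the scale of the straightness score.
    """

    points: np.ndarray  # (n, 2)
    body_length_ref: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise SchemaError(f"edge points must be (n, 2), got {pts.shape}")
        if len(pts) < 5:
            raise InsufficientEdgeError(
                f"back edge needs >= 5 points, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise SchemaError("edge points must be finite")
        if not (self.body_length_ref > 0):
            raise SchemaError("body_length_ref must be > 0")
        order = np.argsort(pts[:, 0], kind="stable")
        object.__setattr__(self, "points", pts[order])


def back_straightness_score(edge: BackEdge, lam: float = DEFAULT_BACK_LAMBDA) -> float:
    """Score how straight a back edge is, in [0, 1].

    The total-least-squares line is fitted to the edge points; the RMS of
    the perpendicular residuals, normalized by body length, is mapped
    through ``exp(-rms / (lam * body_length))`` so that a perfectly straight
    edge scores 1 and deeper arching scores monotonically lower.  The score
    is invariant to rigid motion and to uniform scaling of the edge together
    with its body-length reference.
    """
    pts = edge.points
    centered = pts - pts.mean(axis=0)
    # Perpendicular residuals = projections on the minor principal axis.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    residuals = centered @ vt[1]
    rms = float(np.sqrt(np.mean(residuals**2)))
    return float(np.exp(-rms / (lam * edge.body_length_ref)))


def infer_walking_direction(poses: Sequence[CattlePose]) -> int:
    """Sign (+1/-1) of the net withers x-displacement over a clip.

    Used to normalize hoof–elbow shift signs so that left-to-right and
    right-to-left walks yield identical features.
    """
    if len(poses) < 2:
        return 1
    dx = poses[-1].keypoints["withers"].x - poses[0].keypoints["withers"].x
    return 1 if dx >= 0 else -1


def extract_gait_features(
    pose: CattlePose,
    walking_direction_sign: int = 1,
    back_edge: BackEdge | None = None,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    back_lambda: float = DEFAULT_BACK_LAMBDA,
) -> GaitFeatureVector:
    """Compute the per-frame gait feature vector from a side-view pose.

    Step sizes are horizontal (along-corridor) hoof separations normalized
    by body length; shifts are signed horizontal elbow-minus-hoof offsets
    per leg (sign normalized by walking direction); head position is head
    height above the hoof ground line, normalized by the mean vertical
    hoof–elbow extent.  Features depending on a keypoint below the
    confidence floor are NaN.  ``back_straightness`` is NaN unless a
    ``back_edge`` is supplied.
    """
    if walking_direction_sign not in (+1, -1):
        raise ValueError("walking_direction_sign must be +1 or -1")
    kp = pose.keypoints

    def ok(*names: str) -> bool:
        return all(kp[n].confidence >= confidence_floor for n in names)

    if not ok("withers", "pin"):
        raise DegeneratePoseError(
            "withers/pin below confidence floor: body length undefined"
        )
    w, p = kp["withers"], kp["pin"]
    body_length = math.hypot(w.x - p.x, w.y - p.y)
    if body_length <= 1e-9:
        raise DegeneratePoseError("withers and pin coincide: zero body length")

    def step(front: str, back: str) -> float:
        if not ok(front, back):
            return math.nan
        return abs(kp[front].x - kp[back].x) / body_length

    def shift(elbow: str, hoof: str) -> float:
        if not ok(elbow, hoof):
            return math.nan
        return walking_direction_sign * (kp[elbow].x - kp[hoof].x) / body_length

    hooves = ("fr_hoof", "fl_hoof", "br_hoof", "bl_hoof")
    legs = (
        ("fr_elbow", "fr_hoof"),
        ("fl_elbow", "fl_hoof"),
        ("br_elbow", "br_hoof"),
        ("bl_elbow", "bl_hoof"),
    )
    head_position = math.nan
    if ok("head", *hooves) and all(ok(e) for e, _ in legs):
        ground_y = sum(kp[h].y for h in hooves) / 4.0
        leg_height = sum(abs(kp[h].y - kp[e].y) for e, h in legs) / 4.0
        if leg_height > 1e-9:
            head_position = (ground_y - kp["head"].y) / leg_height

    back = math.nan
    if back_edge is not None:
        back = back_straightness_score(back_edge, lam=back_lambda)

    return GaitFeatureVector(
        body_length=body_length,
        right_step=step("fr_hoof", "br_hoof"),
        left_step=step("fl_hoof", "bl_hoof"),
        head_position=head_position,
        fr_shift=shift("fr_elbow", "fr_hoof"),
        fl_shift=shift("fl_elbow", "fl_hoof"),
        br_shift=shift("br_elbow", "br_hoof"),
        bl_shift=shift("bl_elbow", "bl_hoof"),
        back_straightness=back,
    )


def feature_matrix(features: Sequence[GaitFeatureVector]) -> np.ndarray:
    """Stack per-frame features into an (N, 8) classifier input matrix."""
    return np.array([fv.ls_row() for fv in features], dtype=float)


@dataclass(frozen=True)
class LocomotionWindow:
    """One rolling window of the 8 locomotion features."""

    features: np.ndarray  # (window_length, 8)
    start_frame: int

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 2 or f.shape[0] < 2:
            raise SchemaError(f"window must be (>=2, n_features), got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise SchemaError("window contains missing values")
        object.__setattr__(self, "features", f)


def _fill_gaps(rows: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate missing rows over gaps <= max_gap; return (filled, valid)."""
    rows = rows.copy()
    missing = ~np.all(np.isfinite(rows), axis=1)
    valid = ~missing
    idx = np.flatnonzero(missing)
    if idx.size:
        # contiguous runs of missing frames
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= len(rows) or len(run) > max_gap:
                continue  # unbridgeable: stays invalid, splits the sequence
            t = (run - lo) / (hi - lo)
            rows[run] = rows[lo] + t[:, None] * (rows[hi] - rows[lo])
            valid[run] = True
    return rows, valid


def build_windows(
    feature_rows: np.ndarray | Sequence[Sequence[float]],
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    max_gap: int = DEFAULT_MAX_GAP,
    start_frame: int = 0,
) -> list[LocomotionWindow]:
    """Cut a per-frame feature sequence into rolling windows.

    Within each contiguous valid segment of N frames the window count is
    ``floor((N - window) / stride) + 1`` (0 if N < window).  Frames with
    missing features are linearly interpolated when the gap is at most
    ``max_gap`` frames and bracketed by valid frames; longer gaps split the
    sequence into independent segments.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = np.asarray(feature_rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError(f"feature_rows must be 2-D, got shape {rows.shape}")
    if len(rows) == 0:
        return []
    rows, valid = _fill_gaps(rows, max_gap)

    windows: list[LocomotionWindow] = []
    # walk contiguous valid segments
    boundaries = np.flatnonzero(np.diff(valid.astype(int)) != 0) + 1
    segments = np.split(np.arange(len(rows)), boundaries)
    for seg in segments:
        if len(seg) == 0 or not valid[seg[0]]:
            continue
        n = len(seg)
        if n < window:
            continue
        for s in range(0, n - window + 1, stride):
            lo = seg[0] + s
            windows.append(
                LocomotionWindow(features=rows[lo : lo + window], start_frame=start_frame + lo)
            )
    if not windows:
        logger.warning(
            "sequence of %d frames yields no windows (window=%d)", len(rows), window
        )
    return windows


def _window_summary(w: LocomotionWindow) -> np.ndarray:
    """Pooled summary statistics used as classifier input: per-channel mean,
    std, min, max, and mean absolute first difference."""
    f = w.features
    return np.concatenate(
        [
            f.mean(axis=0),
            f.std(axis=0),
            f.min(axis=0),
            f.max(axis=0),
            np.abs(np.diff(f, axis=0)).mean(axis=0),
        ]
    )


@dataclass
class SequenceClassifier:
    """Pluggable window scorer: pooled statistics + gradient-boosted trees.

    Emits a continuous score in [1, 5] as the probability-weighted mean of
    the 5 locomotion classes, so that the clip-level mean over windows is
    well defined.
    """

    model: HistGradientBoostingClassifier
    classes_: np.ndarray
    seed: int

    def score_window(self, window: LocomotionWindow) -> float:
        return float(self.score_windows([window])[0])

    def score_windows(self, windows: Sequence[LocomotionWindow]) -> np.ndarray:
        X = np.array([_window_summary(w) for w in windows])
        proba = self.model.predict_proba(X)
        scores = proba @ self.classes_.astype(float)
        return np.clip(scores, 1.0, 5.0)

    def predict_class(self, windows: Sequence[LocomotionWindow]) -> np.ndarray:
        X = np.array([_window_summary(w) for w in windows])
        return self.model.predict(X)


def train_sequence_classifier(
    windows: Sequence[LocomotionWindow],
    labels: Sequence[int],
    seed: int = 0,
) -> SequenceClassifier:
    """Fit the window classifier on labeled windows (labels in 1..5).

    Deterministic for a given seed: the same data and seed reproduce the
    same fitted model and predictions.
    """
    if len(windows) != len(labels):
        raise ValueError("windows and labels must have equal length")
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0 or np.unique(labels).size < 2:
        raise DegenerateTrainingError(
            "training requires at least two distinct locomotion classes"
        )
    if labels.min() < 1 or labels.max() > 5:
        raise ValueError("labels must lie in 1..5")
    shapes = {w.features.shape for w in windows}
    if len(shapes) > 1:
        raise ValueError(f"all windows must share a shape, got {shapes}")
    X = np.array([_window_summary(w) for w in windows])
    model = HistGradientBoostingClassifier(max_iter=150, random_state=seed)
    model.fit(X, labels)
    return SequenceClassifier(model=model, classes_=model.classes_, seed=seed)


@dataclass(frozen=True)
class ClipScore:
    """Window scores for one clip and their mean, on the 1–5 scale."""

    window_scores: tuple[float, ...]
    clip_score: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.window_scores) == 0:
            raise ValueError("cannot score a clip with no windows")
        object.__setattr__(
            self, "clip_score", float(np.mean(self.window_scores))
        )


def score_clip(window_scores: Sequence[float]) -> ClipScore:
    """Aggregate window scores into a clip score (unrounded arithmetic mean)."""
    return ClipScore(window_scores=tuple(float(s) for s in window_scores))
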