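"""Pig pen behavioral analytics.

Pixel tracks from an upstream detector/tracker are mapped to pen
coordinates (centimeters) through a four-corner perspective transform.
From the world-frame tracks the module accounts posture time budgets and
the distance traveled by standing pigs, repairs identities after
occlusions using each pig's coordinate history, and detects interactions:
animal–animal contact from bounding-box overlap, confirmed by motion,
posture change, or a drop in structural similarity between consecutive
frames, with a fine-grained label from body-part IoU; animal–enrichment
contact from mask overlap (or displacement, for the ball).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.metrics import structural_similarity
from skimage.transform import ProjectiveTransform

from .errors import DegenerateGeometryError, SchemaError
from .types import ENRICHMENT_NAMES, PenConfig, Point, TrackFrame, _collinear

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_THRESHOLD = 0.10  # fraction of the smaller bbox
DEFAULT_SSIM_THRESHOLD = 0.90
DEFAULT_MOVE_GATE_CM = 2.0
DEFAULT_BALL_MOVE_GATE_CM = 3.0
DEFAULT_MAX_SPEED_CM_S = 300.0
DEFAULT_MIN_PART_IOU = 0.02
DEFAULT_GATE_CM = 50.0
DEFAULT_HISTORY_LEN = 30  # frames (2 s at 15 fps)
DEFAULT_PEN_MARGIN_CM = 20.0
DEFAULT_GAP_BRIDGE_S = 1.0

FineLabel = Literal[
    "mouth_to_tail",
    "mouth_to_ear",
    "mouth_to_body",
    "head_to_head",
    "body_contact",
    "unclassified",
]


@dataclass(frozen=True)
class WorldTransform:
    """Projective map between image pixels and pen centimeters."""

    H: np.ndarray  # 3x3, pixel -> cm

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if H.shape != (3, 3) or abs(np.linalg.det(H)) < 1e-12:
            raise DegenerateGeometryError("transform matrix must be 3x3 and invertible")
        object.__setattr__(self, "H", H)

    def _apply(self, M: np.ndarray, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        homog = np.hstack([pts, np.ones((len(pts), 1))])
        out = homog @ M.T
        return out[:, :2] / out[:, 2:3]

    def to_world(self, points_px) -> np.ndarray:
        """Map pixel points to (x_cm, y_cm)."""
        return self._apply(self.H, points_px)

    def to_pixel(self, points_cm) -> np.ndarray:
        """Map world points back to pixels."""
        return self._apply(np.linalg.inv(self.H), points_cm)


def compute_world_transform(
    corners_px: Sequence[Point], world_dims: tuple[float, float]
) -> WorldTransform:
    """Fit the 4-point perspective transform from pen corners to the world
    rectangle ((0,0), (L,0), (L,W), (0,W)), corners in configured order."""
    corners = np.asarray(corners_px, dtype=float)
    if corners.shape != (4, 2):
        raise DegenerateGeometryError(f"need 4 corner points, got shape {corners.shape}")
    for i in range(4):
        trio = [tuple(corners[j]) for j in range(4) if j != i]
        if _collinear(*trio):
            raise DegenerateGeometryError(f"pen corners are collinear: {corners.tolist()}")
    L, W = world_dims
    dst = np.array([(0.0, 0.0), (L, 0.0), (L, W), (0.0, W)])
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(corners, dst)
        if not tform:
            raise DegenerateGeometryError("projective transform estimation failed")
    else:  # older scikit-image
        tform = ProjectiveTransform()
        if not tform.estimate(corners, dst):
            raise DegenerateGeometryError("projective transform estimation failed")
    wt = WorldTransform(H=tform.params)
    err = np.abs(wt.to_world(corners) - dst).max()
    if err > 1e-6:
        raise DegenerateGeometryError(f"corner mapping residual {err:.2e} cm exceeds 1e-6")
    return wt


def track_to_world(
    track: Sequence[TrackFrame],
    transform: WorldTransform,
    world_dims: tuple[float, float] | None = None,
    margin_cm: float = DEFAULT_PEN_MARGIN_CM,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a track's centroids to pen centimeters.

    Returns ``(world_xy, outside)`` where ``outside`` flags frames whose
    mapped centroid falls beyond ``margin_cm`` outside the pen rectangle
    (only checked when ``world_dims`` is given).
    """
    if len(track) == 0:
        return np.empty((0, 2)), np.empty(0, dtype=bool)
    world = transform.to_world([tf.centroid for tf in track])
    if world_dims is None:
        outside = np.zeros(len(world), dtype=bool)
    else:
        L, W = world_dims
        outside = (
            (world[:, 0] < -margin_cm)
            | (world[:, 0] > L + margin_cm)
            | (world[:, 1] < -margin_cm)
            | (world[:, 1] > W + margin_cm)
        )
        if outside.any():
            logger.warning("%d/%d track points map outside the pen margin", outside.sum(), len(world))
    return world, outside


@dataclass(frozen=True)
class DistanceResult:
    """Standing-travel distance plus the tracker-glitch diagnostics tally."""

    distance_cm: float
    dropped_steps: int


def distance_traveled(
    world_track: np.ndarray,
    postures: Sequence[str],
    fps: float,
    max_speed_cm_s: float = DEFAULT_MAX_SPEED_CM_S,
) -> DistanceResult:
    """Euclidean distance traveled while standing, in centimeters.

    A step contributes only when both of its endpoint frames are standing;
    steps implying a speed above ``max_speed_cm_s`` are treated as tracker
    glitches — dropped from the total and counted in the diagnostics tally.
    """
    world = np.asarray(world_track, dtype=float).reshape(-1, 2)
    if len(world) != len(postures):
        raise ValueError(
            f"track ({len(world)}) and postures ({len(postures)}) lengths differ"
        )
    if len(world) < 2:
        return DistanceResult(0.0, 0)
    steps = np.linalg.norm(np.diff(world, axis=0), axis=1)
    standing = np.asarray([p == "standing" for p in postures], dtype=bool)
    eligible = standing[:-1] & standing[1:]
    glitch = eligible & (steps * fps > max_speed_cm_s)
    total = float(steps[eligible & ~glitch].sum())
    return DistanceResult(total, int(glitch.sum()))


def posture_budget(postures: Sequence[str], fps: float) -> tuple[float, float]:
    """Seconds spent standing and lying; the two sum to N/fps exactly."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    n_stand = sum(1 for p in postures if p == "standing")
    n_lie = len(postures) - n_stand
    return n_stand / fps, n_lie / fps


def reassign_after_occlusion(
    frames: Mapping[int, Sequence[TrackFrame]],
    transform: WorldTransform,
    history_len: int = DEFAULT_HISTORY_LEN,
    gate_cm: float = DEFAULT_GATE_CM,
) -> tuple[dict[int, list[TrackFrame]], dict[int, int]]:
    """Repair tracker identities after occlusions using coordinate history.

    When a track id disappears and a new id appears within ``gate_cm`` of
    the lost id's last world position within ``history_len`` frames, the
    new id is relabeled to the lost one.  Multiple simultaneous candidates
    are resolved greedily by smallest distance first.  Returns the
    relabeled frames and the applied ``{new_id: original_id}`` map.
    """
    relabel: dict[int, int] = {}
    # per (canonical) id: last world position and last frame seen
    last_pos: dict[int, np.ndarray] = {}
    last_frame: dict[int, int] = {}
    seen: set[int] = set()
    out: dict[int, list[TrackFrame]] = {}

    for fidx in sorted(frames):
        group = frames[fidx]
        canon_ids = {relabel.get(tf.animal_track_id, tf.animal_track_id) for tf in group}
        new_raw = [
            tf
            for tf in group
            if tf.animal_track_id not in seen and tf.animal_track_id not in relabel
        ]
        lost = [
            cid
            for cid in last_pos
            if cid not in canon_ids and fidx - last_frame[cid] <= history_len
        ]
        if new_raw and lost:
            pairs = []
            for tf in new_raw:
                w = transform.to_world([tf.centroid])[0]
                for cid in lost:
                    d = float(np.linalg.norm(w - last_pos[cid]))
                    if d <= gate_cm:
                        pairs.append((d, tf.animal_track_id, cid))
            pairs.sort()
            used_new: set[int] = set()
            used_lost: set[int] = set()
            for d, nid, cid in pairs:
                if nid in used_new or cid in used_lost:
                    continue
                relabel[nid] = cid
                used_new.add(nid)
                used_lost.add(cid)
        relabeled = []
        for tf in group:
            cid = relabel.get(tf.animal_track_id, tf.animal_track_id)
            seen.add(tf.animal_track_id)
            if cid != tf.animal_track_id:
                tf = tf.model_copy(update={"animal_track_id": cid})
            relabeled.append(tf)
            last_pos[cid] = transform.to_world([tf.centroid])[0]
            last_frame[cid] = fidx
        out[fidx] = relabeled
    return out, relabel


def detect_contact(
    bbox_a: Sequence[float],
    bbox_b: Sequence[float],
    overlap_frac_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> tuple[bool, float]:
    """Bounding-box contact test.

    The overlap fraction is the intersection area over the *smaller* box's
    area, so that a small animal's head inside a large animal's box still
    registers; contact holds when the fraction reaches the threshold.
    Symmetric in its arguments.
    """

    def area(bb):
        w, h = bb[2] - bb[0], bb[3] - bb[1]
        if w <= 0 or h <= 0:
            raise SchemaError(f"zero-area bbox {tuple(bb)}")
        return w * h

    a_area, b_area = area(bbox_a), area(bbox_b)
    ix = min(bbox_a[2], bbox_b[2]) - max(bbox_a[0], bbox_b[0])
    iy = min(bbox_a[3], bbox_b[3]) - max(bbox_a[1], bbox_b[1])
    inter = max(0.0, ix) * max(0.0, iy)
    frac = inter / min(a_area, b_area)
    return frac >= overlap_frac_threshold, float(frac)


def confirm_interaction(
    prev_crop: Optional[np.ndarray],
    cur_crop: Optional[np.ndarray],
    centroid_step_cm: tuple[float, float],
    posture_changed: tuple[bool, bool],
    ssim_threshold: float = DEFAULT_SSIM_THRESHOLD,
    move_gate_cm: float = DEFAULT_MOVE_GATE_CM,
) -> bool:
    """Confirm a bbox contact as a genuine interaction.

    Confirmation requires movement evidence from either animal: a centroid
    step above ``move_gate_cm``, a posture change, or — when grayscale
    crops over the union bbox are available — structural similarity between
    the previous and current crops below ``ssim_threshold``.  Without
    crops the SSIM term is skipped.
    """
    if max(centroid_step_cm) > move_gate_cm or any(posture_changed):
        return True
    if prev_crop is None or cur_crop is None:
        return False
    prev_crop = np.asarray(prev_crop)
    cur_crop = np.asarray(cur_crop)
    if prev_crop.shape != cur_crop.shape:
        raise SchemaError(
            f"crop shapes differ: {prev_crop.shape} vs {cur_crop.shape}"
        )
    if min(prev_crop.shape) < 7:
        return False  # too small for the 7x7 SSIM window
    ssim = structural_similarity(
        prev_crop,
        cur_crop,
        win_size=7,
        gaussian_weights=True,
        sigma=1.5,
        data_range=255 if prev_crop.dtype == np.uint8 else float(
            max(prev_crop.max(), cur_crop.max()) - min(prev_crop.min(), cur_crop.min()) or 1.0
        ),
    )
    return bool(ssim < ssim_threshold)


def _poly(points: Sequence[Point]) -> Polygon:
    p = Polygon(points)
    if not p.is_valid:
        p = p.buffer(0)
    return p


def part_iou(poly_a: Sequence[Point], poly_b: Sequence[Point]) -> float:
    """Intersection-over-union of two part polygons (pixel space)."""
    pa, pb = _poly(poly_a), _poly(poly_b)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def _part_kind(name: str) -> str:
    return "ear" if name in ("left_ear", "right_ear") else name


_HEAD = {"mouth", "ear"}


def _label_for_pair(kind_a: str, kind_b: str) -> FineLabel:
    kinds = {kind_a, kind_b}
    if kinds == {"mouth", "tail"}:
        return "mouth_to_tail"
    if kinds == {"mouth", "ear"} or kinds == {"mouth"}:
        return "head_to_head" if kinds == {"mouth"} else "mouth_to_ear"
    if kinds == {"mouth", "body"}:
        return "mouth_to_body"
    if kinds <= _HEAD:
        return "head_to_head"
    # tail/ear/body combinations other than the above: generic contact
    return "body_contact"


def classify_fine_interaction(
    parts_a: Mapping[str, Sequence[Point]],
    parts_b: Mapping[str, Sequence[Point]],
    min_iou: float = DEFAULT_MIN_PART_IOU,
) -> tuple[FineLabel, Optional[str]]:
    """Label an animal–animal contact from body-part polygon IoU.

    The cross pair of parts with maximal IoU above ``min_iou`` determines
    the label (mouth–tail, mouth–ear, mouth–body, head-to-head, or generic
    body contact); below ``min_iou`` the contact stays ``unclassified``.
    The label is symmetric in the two animals; the second element reports
    the actor ("a" or "b") when the mouth in the selected pair belongs to
    exactly one animal, else ``None``.  Ties between pairs resolve by part
    name order, deterministically.
    """
    if "body" not in parts_a and "body" not in parts_b:
        raise SchemaError("both animals lack a body polygon")
    best: tuple[float, str, str] | None = None
    for na in sorted(parts_a):
        for nb in sorted(parts_b):
            iou = part_iou(parts_a[na], parts_b[nb])
            if iou >= min_iou and (best is None or iou > best[0]):
                best = (iou, na, nb)
    if best is None:
        return "unclassified", None
    _, na, nb = best
    ka, kb = _part_kind(na), _part_kind(nb)
    label = _label_for_pair(ka, kb)
    actor = None
    if ka == "mouth" and kb != "mouth":
        actor = "a"
    elif kb == "mouth" and ka != "mouth":
        actor = "b"
    return label, actor


def detect_enrichment_interaction(
    animal_mask: Sequence[Point],
    enrichment_name: str,
    enrichment_polygon: Sequence[Point],
    ball_step_cm: Optional[float] = None,
    ball_move_gate_cm: float = DEFAULT_BALL_MOVE_GATE_CM,
) -> bool:
    """Animal–enrichment interaction test.

    Non-ball fixtures interact when the animal mask overlaps the fixture
    polygon; the ball additionally interacts when it moved more than
    ``ball_move_gate_cm`` since the previous frame.
    """
    if enrichment_name not in ENRICHMENT_NAMES:
        raise SchemaError(
            f"unknown enrichment {enrichment_name!r}; expected one of {sorted(ENRICHMENT_NAMES)}"
        )
    overlap = _poly(animal_mask).intersection(_poly(enrichment_polygon)).area > 0.0
    if enrichment_name == "ball" and ball_step_cm is not None:
        return overlap or ball_step_cm > ball_move_gate_cm
    return overlap


@dataclass(frozen=True)
class InteractionEvent:
    """A contiguous confirmed interaction between two animals or an animal
    and an enrichment fixture."""

    frame_span: tuple[int, int]
    participants: tuple[int, int] | tuple[int, str]
    kind: Literal["animal_animal", "enrichment"]
    confirmed: bool = True
    fine_label: Optional[FineLabel] = None
    actor: Optional[int] = None

    def __post_init__(self) -> None:
        s, e = self.frame_span
        if s > e:
            raise SchemaError(f"event span {self.frame_span} has start > end")
        if self.kind == "enrichment" and self.fine_label is not None:
            raise SchemaError("fine_label applies only to animal_animal events")

    @property
    def n_frames(self) -> int:
        return self.frame_span[1] - self.frame_span[0] + 1


@dataclass
class InteractionParams:
    """Tunable thresholds of the interaction detector."""

    overlap_frac_threshold: float = DEFAULT_OVERLAP_THRESHOLD
    ssim_threshold: float = DEFAULT_SSIM_THRESHOLD
    move_gate_cm: float = DEFAULT_MOVE_GATE_CM
    min_part_iou: float = DEFAULT_MIN_PART_IOU
    ball_move_gate_cm: float = DEFAULT_BALL_MOVE_GATE_CM
    gap_bridge_s: float = DEFAULT_GAP_BRIDGE_S


def _union_bbox(b1, b2) -> tuple[int, int, int, int]:
    return (
        int(np.floor(min(b1[0], b2[0]))),
        int(np.floor(min(b1[1], b2[1]))),
        int(np.ceil(max(b1[2], b2[2]))),
        int(np.ceil(max(b1[3], b2[3]))),
    )


def _crop(frame: np.ndarray, bbox) -> np.ndarray:
    x0, y0, x1, y1 = bbox
    h, w = frame.shape[:2]
    return frame[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)]


def detect_interactions(
    frames: Mapping[int, Sequence[TrackFrame]],
    pen: PenConfig,
    transform: WorldTransform,
    frame_images: Optional[Mapping[int, np.ndarray]] = None,
    params: InteractionParams | None = None,
    fps: float | None = None,
) -> list[InteractionEvent]:
    """Run the full per-frame interaction pipeline over a track stream.

    For every frame and animal pair, bbox contact is tested, confirmed by
    motion / posture change / SSIM (grayscale ``frame_images`` optional),
    and labeled from part IoU; animal–enrichment overlap is tested against
    the configured fixture polygons.  Consecutive confirmed frames of the
    same pair merge into one event; gaps up to ``gap_bridge_s`` seconds are
    bridged.  An event's fine label is the most frequent per-frame label.
    """
    params = params or InteractionParams()
    fps = fps or pen.fps
    gap_frames = int(round(params.gap_bridge_s * fps))
    if frame_images is None:
        logger.info("no frame images supplied; SSIM confirmation skipped")

    # per-animal world positions and postures by frame, for motion evidence
    prev_state: dict[int, tuple[np.ndarray, str]] = {}
    # key -> list of confirmed frames / per-frame labels
    confirmed_frames: dict[tuple, list[int]] = defaultdict(list)
    frame_labels: dict[tuple, dict[int, tuple[FineLabel, Optional[int]]]] = defaultdict(dict)

    frame_indices = sorted(frames)
    for prev_idx, fidx in zip([None] + frame_indices[:-1], frame_indices):
        group = sorted(frames[fidx], key=lambda tf: tf.animal_track_id)
        state = {
            tf.animal_track_id: (transform.to_world([tf.centroid])[0], tf.posture)
            for tf in group
        }
        for i, tf_a in enumerate(group):
            for tf_b in group[i + 1 :]:
                contact, _ = detect_contact(
                    tf_a.bbox, tf_b.bbox, params.overlap_frac_threshold
                )
                if not contact:
                    continue
                steps = []
                changed = []
                for tf in (tf_a, tf_b):
                    aid = tf.animal_track_id
                    if aid in prev_state:
                        w_prev, p_prev = prev_state[aid]
                        steps.append(float(np.linalg.norm(state[aid][0] - w_prev)))
                        changed.append(tf.posture != p_prev)
                    else:
                        steps.append(0.0)
                        changed.append(False)
                prev_img = cur_img = None
                if frame_images is not None and prev_idx is not None:
                    fi_prev = frame_images.get(prev_idx)
                    fi_cur = frame_images.get(fidx)
                    if fi_prev is not None and fi_cur is not None:
                        ub = _union_bbox(tf_a.bbox, tf_b.bbox)
                        prev_img, cur_img = _crop(fi_prev, ub), _crop(fi_cur, ub)
                ok = confirm_interaction(
                    prev_img,
                    cur_img,
                    (steps[0], steps[1]),
                    (changed[0], changed[1]),
                    params.ssim_threshold,
                    params.move_gate_cm,
                )
                if not ok:
                    continue
                key = ("aa", tf_a.animal_track_id, tf_b.animal_track_id)
                confirmed_frames[key].append(fidx)
                if tf_a.parts and tf_b.parts:
                    label, actor = classify_fine_interaction(
                        tf_a.parts, tf_b.parts, params.min_part_iou
                    )
                    actor_id = {
                        "a": tf_a.animal_track_id,
                        "b": tf_b.animal_track_id,
                        None: None,
                    }[actor]
                    frame_labels[key][fidx] = (label, actor_id)
            # enrichment
            mask = (tf_a.parts or {}).get("body") or _bbox_polygon(tf_a.bbox)
            for name, poly in pen.enrichment.items():
                if detect_enrichment_interaction(mask, name, poly):
                    confirmed_frames[("en", tf_a.animal_track_id, name)].append(fidx)
        prev_state = state

    events: list[InteractionEvent] = []
    for key, fr in confirmed_frames.items():
        for lo, hi in _merge_spans(fr, gap_frames):
            if key[0] == "aa":
                span_labels = [
                    lv for f, lv in frame_labels.get(key, {}).items() if lo <= f <= hi
                ]
                fine, actor = _consensus_label(span_labels)
                events.append(
                    InteractionEvent(
                        frame_span=(lo, hi),
                        participants=(key[1], key[2]),
                        kind="animal_animal",
                        fine_label=fine,
                        actor=actor,
                    )
                )
            else:
                events.append(
                    InteractionEvent(
                        frame_span=(lo, hi),
                        participants=(key[1], key[2]),
                        kind="enrichment",
                    )
                )
    events.sort(key=lambda e: (e.frame_span, str(e.participants)))
    return events


def _bbox_polygon(bbox) -> list[Point]:
    x0, y0, x1, y1 = bbox
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


def _merge_spans(frames_list: Sequence[int], gap: int) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    for f in sorted(frames_list):
        if spans and f - spans[-1][1] <= gap + 1:
            spans[-1] = (spans[-1][0], f)
        else:
            spans.append((f, f))
    return spans


def _consensus_label(
    labels: Sequence[tuple[FineLabel, Optional[int]]]
) -> tuple[FineLabel, Optional[int]]:
    informative = [lv for lv in labels if lv[0] != "unclassified"]
    pool = informative or list(labels)
    if not pool:
        return "unclassified", None
    (label, actor), _ = Counter(pool).most_common(1)[0]
    return label, actor


@dataclass
class ActivityReport:
    """Per-animal activity summary and hourly interaction-minutes matrix."""

    per_animal: pd.DataFrame  # index animal id; standing_s, lying_s, distance_cm
    hourly_interaction_min: pd.DataFrame  # index animal id; columns hour bins


def build_activity_report(
    events: Sequence[InteractionEvent],
    budgets: Mapping[int, tuple[float, float]],
    distances: Mapping[int, float],
    fps: float,
    bin_hours: float = 1.0,
) -> ActivityReport:
    """Assemble the pen activity report.

    Interaction minutes are attributed frame by frame to wall-clock hour
    bins (bin width ``bin_hours``), for each animal participant of each
    confirmed event, so that the total over bins equals the total event
    duration exactly.
    """
    animals = sorted(budgets)
    per_animal = pd.DataFrame(
        {
            "standing_s": [budgets[a][0] for a in animals],
            "lying_s": [budgets[a][1] for a in animals],
            "distance_cm": [float(distances.get(a, 0.0)) for a in animals],
        },
        index=pd.Index(animals, name="animal"),
    )
    frames_per_bin = fps * 3600.0 * bin_hours
    cells: dict[tuple[int, int], float] = defaultdict(float)
    max_bin = 0
    for ev in events:
        if not ev.confirmed:
            continue
        pigs = [p for p in ev.participants if isinstance(p, int)]
        lo, hi = ev.frame_span
        for f in range(lo, hi + 1):
            b = int(f // frames_per_bin)
            max_bin = max(max_bin, b)
            for p in pigs:
                cells[(p, b)] += 1.0 / fps / 60.0
    hourly = pd.DataFrame(
        0.0,
        index=pd.Index(animals, name="animal"),
        columns=pd.RangeIndex(max_bin + 1, name="hour_bin"),
    )
    for (p, b), minutes in cells.items():
        if p in hourly.index:
            hourly.loc[p, b] = minutes
    return ActivityReport(per_animal=per_animal, hourly_interaction_min=hourly)
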