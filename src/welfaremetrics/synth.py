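"""Seeded synthetic generators for every input the analysis modules consume.

These generators emulate the *outputs* of the upstream detection stack —
pose keypoints, back-silhouette edges, track records, embedding points,
tag colors — with controllable ground truth, so the analytic pipeline is
testable end to end without cameras or trained networks.  Every generator
is a pure function of its script and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .colorid import LabColor
from .gait import BackEdge
from .pig import InteractionEvent, WorldTransform, compute_world_transform
from .types import (
    AnimalTemplate,
    CattlePose,
    DEFAULT_EXTRA_KEYPOINTS,
    Keypoint,
    PenConfig,
    PIG_FPS,
    TrackFrame,
)

# ---------------------------------------------------------------------------
# Cattle gait sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitScript:
    """Parameters of one synthetic side-view walking clip.

    ``lameness_level`` (1 normal … 5 severely lame) controls three gait
    signatures simultaneously: step-length asymmetry between the right and
    left diagonal pairs, vertical head-bob amplitude, and back-arch sagitta.
    """

    lameness_level: int
    n_frames: int = 120
    fps: float = 20.0
    noise_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.lameness_level <= 5):
            raise ValueError("lameness_level must be in 1..5")
        if self.noise_px < 0:
            raise ValueError("noise_px must be >= 0")


# skeleton geometry (pixels): cow walks toward +x
_BODY_LENGTH = 200.0
_WITHERS_Y = 200.0
_ELBOW_Y = 300.0
_HOOF_Y = 380.0
_HEAD_DY = -60.0  # head above withers
_STEP_AMP = 18.0  # hoof swing amplitude, px
_WALK_SPEED = 3.0  # px per frame
#: Per-level fractional amplitude deficit of the lame (front-right) leg.
_LAME_DEFICIT = 0.12
#: Per-level head-bob amplitude increment (px).
_BOB_STEP = 3.0
#: Per-level back-arch sagitta as a fraction of body length.
_SAGITTA_STEP = 0.05
_N_EDGE_POINTS = 21


def gen_gait_sequence(
    script: GaitScript,
) -> tuple[list[CattlePose], list[BackEdge], int]:
    """Generate a synthetic walking clip: poses, back edges, true level.

    Leg kinematics are sinusoidal with diagonal phasing; the front-right
    leg's swing amplitude shrinks with lameness level (step asymmetry), the
    head bobs with amplitude growing with level, and the back edge is a
    parabolic arc whose sagitta grows with level (level 1 is flat).
    Gaussian pixel noise of ``script.noise_px`` is added to every
    coordinate.  Deterministic per seed.
    """
    rng = np.random.default_rng(script.seed)
    lvl = script.lameness_level
    amp_fr = _STEP_AMP * (1.0 - _LAME_DEFICIT * (lvl - 1))
    bob = _BOB_STEP * (lvl - 1)
    sagitta = _SAGITTA_STEP * (lvl - 1) * _BODY_LENGTH
    omega = 2.0 * np.pi * 1.0 / script.fps  # one stride cycle per second

    poses: list[CattlePose] = []
    edges: list[BackEdge] = []
    for f in range(script.n_frames):
        phase = omega * f
        x0 = 100.0 + _WALK_SPEED * f  # pin (rear) reference
        pin = (x0, _WITHERS_Y)
        withers = (x0 + _BODY_LENGTH, _WITHERS_Y)
        head = (x0 + _BODY_LENGTH + 100.0, _WITHERS_Y + _HEAD_DY + bob * np.sin(phase))
        fr_ex, fl_ex = withers[0] - 15.0, withers[0] - 25.0
        br_ex, bl_ex = x0 + 15.0, x0 + 25.0
        s, c = np.sin(phase), np.sin(phase + np.pi)
        kp = {
            "head": head,
            "withers": withers,
            "pin": pin,
            "fr_elbow": (fr_ex, _ELBOW_Y),
            "fl_elbow": (fl_ex, _ELBOW_Y),
            "br_elbow": (br_ex, _ELBOW_Y),
            "bl_elbow": (bl_ex, _ELBOW_Y),
            # diagonal pairs in phase: fr/bl vs fl/br
            "fr_hoof": (fr_ex + amp_fr * s, _HOOF_Y),
            "fl_hoof": (fl_ex + _STEP_AMP * c, _HOOF_Y),
            "br_hoof": (br_ex + _STEP_AMP * c, _HOOF_Y),
            "bl_hoof": (bl_ex + _STEP_AMP * s, _HOOF_Y),
        }
        # non-required slots: simple interpolants along the spine
        extras = {
            "nose": (head[0] + 25.0, head[1] + 10.0),
            "neck": (withers[0] + 50.0, _WITHERS_Y - 20.0),
            "spine_mid": ((withers[0] + pin[0]) / 2.0, _WITHERS_Y - sagitta),
            "tail_base": (pin[0] - 10.0, _WITHERS_Y + 10.0),
            "tail_tip": (pin[0] - 20.0, _ELBOW_Y),
        }
        kp.update(extras)
        noisy = {
            name: Keypoint(
                x=float(x + rng.normal(0.0, script.noise_px) if script.noise_px else x),
                y=float(y + rng.normal(0.0, script.noise_px) if script.noise_px else y),
                confidence=1.0,
            )
            for name, (x, y) in kp.items()
        }
        poses.append(CattlePose(frame_index=f, keypoints=noisy))

        t = np.linspace(0.0, 1.0, _N_EDGE_POINTS)
        ex = pin[0] + t * _BODY_LENGTH
        ey = _WITHERS_Y - sagitta * 4.0 * t * (1.0 - t)  # arch bulges upward
        if script.noise_px:
            ex = ex + rng.normal(0.0, script.noise_px, ex.shape)
            ey = ey + rng.normal(0.0, script.noise_px, ey.shape)
        edges.append(
            BackEdge(points=np.column_stack([ex, ey]), body_length_ref=_BODY_LENGTH)
        )
    return poses, edges, lvl


def step_asymmetry(ls_features: np.ndarray) -> float:
    """Right-vs-left step-amplitude asymmetry of a feature sequence.

    Computed as the absolute difference between the peak-to-peak ranges of
    the right and left normalized step-size columns; grows with the lame
    leg's swing deficit by construction of the generator.
    """
    rows = np.asarray(ls_features, dtype=float)
    right, left = rows[:, 0], rows[:, 1]
    return float(abs(np.ptp(right) - np.ptp(left)))


# ---------------------------------------------------------------------------
# Embedding clusters (open-set identification)
# ---------------------------------------------------------------------------


def gen_embedding_clusters(
    k_ids: int,
    per_id: int,
    sigma: float,
    separation: float,
    dim: int = 3,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Gaussian identity clusters in embedding space.

    Centroids are drawn isotropically then rescaled so the *minimum*
    pairwise distance equals ``separation``; each identity gets ``per_id``
    points at N(centroid, sigma^2 I).  Returns (encodings, centroids) keyed
    by zero-padded string ids.
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    if k_ids < 2:
        raise ValueError("need at least 2 identities")
    rng = np.random.default_rng(seed)
    while True:
        cents = rng.normal(0.0, 1.0, size=(k_ids, dim))
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
        dmin = d[np.triu_indices(k_ids, 1)].min()
        if dmin > 1e-9:
            break
    cents *= separation / dmin
    ids = [f"cow{idx:03d}" for idx in range(k_ids)]
    encodings = {
        aid: cents[i] + rng.normal(0.0, sigma, size=(per_id, dim))
        for i, aid in enumerate(ids)
    }
    centroids = {aid: cents[i].copy() for i, aid in enumerate(ids)}
    return encodings, centroids


# ---------------------------------------------------------------------------
# Pig pen scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptedEvent:
    """One ground-truth behavioral event in a pen script.

    kinds: ``animal_animal`` (participants = two pig indices, with a fine
    label), ``enrichment`` (pig index + fixture name), ``lying`` (one pig
    lies down for the span), ``walk`` (one pig walks ``distance_cm`` along
    the pen during the span).
    """

    start_s: float
    end_s: float
    kind: str
    participants: tuple
    fine_label: Optional[str] = None
    distance_cm: Optional[float] = None


@dataclass(frozen=True)
class PenScript:
    n_pigs: int
    duration_s: float
    fps: float = PIG_FPS
    events: tuple[ScriptedEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for ev in self.events:
            if not (0.0 <= ev.start_s <= ev.end_s < self.duration_s):
                raise ValueError(f"event {ev} outside clip duration")


@dataclass
class PenScene:
    """A generated pen scene with its ground truth."""

    frames: dict[int, list[TrackFrame]]
    frame_images: dict[int, np.ndarray]
    truth_events: list[InteractionEvent]
    truth_distance_cm: dict[int, float]
    truth_lying_frames: dict[int, int]
    pen: PenConfig
    transform: WorldTransform


# schematic camera geometry for synthetic pens (pixels)
_PEN_CORNERS = ((40.0, 30.0), (600.0, 40.0), (590.0, 450.0), (50.0, 440.0))
_IMG_SHAPE = (480, 640)
# pig body half-extent in world cm (length x, width y)
_PIG_HALF = (30.0, 15.0)
_OSC_CM = 2.6  # in-contact oscillation per frame; above the 2 cm move gate
_CONTACT_GAP_CM = 40.0  # centroid separation while in contact (bodies 60 long)


def make_pen(n_pigs: int = 4, with_roster: bool = True) -> PenConfig:
    """A synthetic pen: fixed schematic corners, world 580x380 cm,
    enrichment fixtures near the walls, and a color roster."""
    transform = compute_world_transform(_PEN_CORNERS, (580.0, 380.0))
    # fixtures placed in world cm, stored as pixel polygons
    fixtures_world = {
        "hay": (520.0, 40.0),
        "pole": (520.0, 340.0),
        "ball": (60.0, 340.0),
        "feeder": (60.0, 40.0),
    }
    enrichment = {}
    for name, (wx, wy) in fixtures_world.items():
        corners = [
            (wx - 15.0, wy - 15.0),
            (wx + 15.0, wy - 15.0),
            (wx + 15.0, wy + 15.0),
            (wx - 15.0, wy + 15.0),
        ]
        enrichment[name] = [tuple(p) for p in transform.to_pixel(corners)]
    roster = []
    if with_roster:
        base_colors = [
            (55.0, 70.0, 45.0),   # red tag
            (50.0, -55.0, 40.0),  # green
            (40.0, 20.0, -60.0),  # blue
            (85.0, 5.0, 80.0),    # yellow
            (60.0, 60.0, -40.0),  # magenta
            (75.0, -35.0, -15.0), # cyan
            (30.0, 40.0, 25.0),   # dark red
            (90.0, -5.0, 10.0),   # off-white
            (65.0, 30.0, 60.0),   # orange
            (45.0, -30.0, -45.0), # teal-blue
            (70.0, 45.0, 10.0),   # pink
            (25.0, -20.0, 30.0),  # olive
        ]
        symbols = ("triangle", "circle", "line", "cross")
        for i in range(n_pigs):
            roster.append(
                AnimalTemplate(
                    animal_id=f"pig{i:02d}",
                    lab_color=base_colors[i % len(base_colors)],
                    symbol=symbols[i % 4],
                )
            )
    return PenConfig(
        corners_px=_PEN_CORNERS,
        world_dims=(580.0, 380.0),
        enrichment=enrichment,
        roster=roster,
        fps=PIG_FPS,
    )


def _home_positions(n_pigs: int) -> np.ndarray:
    """Stationary home positions on a central grid, >= 72 cm apart."""
    homes = []
    for i in range(n_pigs):
        col, row = i % 6, i // 6
        homes.append((120.0 + 72.0 * col, 150.0 + 90.0 * row))
    return np.asarray(homes)


def _pig_track_frame(
    fidx: int,
    pid: int,
    world_xy: np.ndarray,
    posture: str,
    transform: WorldTransform,
    parts: Optional[dict] = None,
) -> TrackFrame:
    hx, hy = _PIG_HALF
    corners_w = [
        (world_xy[0] - hx, world_xy[1] - hy),
        (world_xy[0] + hx, world_xy[1] - hy),
        (world_xy[0] + hx, world_xy[1] + hy),
        (world_xy[0] - hx, world_xy[1] + hy),
    ]
    px = transform.to_pixel(corners_w)
    x0, y0 = px.min(axis=0)
    x1, y1 = px.max(axis=0)
    centroid = transform.to_pixel([tuple(world_xy)])[0]
    cx = float(np.clip(centroid[0], x0, x1))
    cy = float(np.clip(centroid[1], y0, y1))
    bbox = (float(x0), float(y0), float(x1), float(y1))
    if parts is None:
        parts = {"body": [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]}
    return TrackFrame(
        frame_index=fidx,
        animal_track_id=pid,
        bbox=bbox,
        centroid=(cx, cy),
        posture=posture,
        parts=parts,
    )


def _square(center: np.ndarray, half: float = 5.0) -> list[tuple[float, float]]:
    cx, cy = float(center[0]), float(center[1])
    return [
        (cx - half, cy - half),
        (cx + half, cy - half),
        (cx + half, cy + half),
        (cx - half, cy + half),
    ]


def _event_parts(
    label: str,
    bbox_a: tuple,
    bbox_b: tuple,
    contact_px: np.ndarray,
) -> tuple[dict, dict]:
    """Part polygons (pixel space) realizing the intended fine label."""
    poly_a = [(bbox_a[0], bbox_a[1]), (bbox_a[2], bbox_a[1]), (bbox_a[2], bbox_a[3]), (bbox_a[0], bbox_a[3])]
    poly_b = [(bbox_b[0], bbox_b[1]), (bbox_b[2], bbox_b[1]), (bbox_b[2], bbox_b[3]), (bbox_b[0], bbox_b[3])]
    sq = _square(contact_px)
    if label == "mouth_to_tail":
        return {"body": poly_a, "mouth": sq}, {"body": poly_b, "tail": sq}
    if label == "mouth_to_ear":
        return {"body": poly_a, "mouth": sq}, {"body": poly_b, "left_ear": sq}
    if label == "head_to_head":
        return {"body": poly_a, "mouth": sq}, {"body": poly_b, "mouth": sq}
    if label == "mouth_to_body":
        # actor's body pulled back so only its mouth reaches the other pig
        inset_a = [
            (bbox_a[0], bbox_a[1]),
            (bbox_b[0] - 2.0, bbox_a[1]),
            (bbox_b[0] - 2.0, bbox_a[3]),
            (bbox_a[0], bbox_a[3]),
        ]
        return {"body": inset_a, "mouth": sq}, {"body": poly_b}
    if label == "body_contact":
        return {"body": poly_a}, {"body": poly_b}
    raise ValueError(f"unknown fine label {label!r}")


def gen_pen_scene(
    script: PenScript, pen: PenConfig | None = None, render: bool = True
) -> PenScene:
    """Generate a scripted pen scene with exact ground truth.

    Pigs rest at fixed home positions; scripted events move them: an
    ``animal_animal`` event teleports the first participant next to the
    second for the span, with overlapping bounding boxes, per-frame
    oscillation above the movement gate, and part polygons realizing the
    intended fine label; an ``enrichment`` event parks the pig on the
    fixture; ``walk`` moves a pig linearly; ``lying`` switches posture.
    Schematic grayscale frames (textured rectangles on a flat background)
    are rendered for frames adjacent to animal contacts so SSIM responds
    to scripted motion.  Deterministic per seed.
    """
    pen = pen or make_pen(script.n_pigs)
    transform = compute_world_transform(pen.corners_px, pen.world_dims)
    n_frames = int(round(script.duration_s * script.fps))
    homes = _home_positions(script.n_pigs)
    rng = np.random.default_rng(script.seed)

    def span(ev: ScriptedEvent) -> tuple[int, int]:
        return (
            int(round(ev.start_s * script.fps)),
            int(round(ev.end_s * script.fps)),
        )

    fixture_world = {
        name: transform.to_world(poly).mean(axis=0)
        for name, poly in pen.enrichment.items()
    }

    frames: dict[int, list[TrackFrame]] = {}
    truth_events: list[InteractionEvent] = []
    truth_distance = {p: 0.0 for p in range(script.n_pigs)}
    truth_lying = {p: 0 for p in range(script.n_pigs)}

    aa_events = [ev for ev in script.events if ev.kind == "animal_animal"]
    for ev in script.events:
        lo, hi = span(ev)
        if ev.kind == "animal_animal":
            a, b = ev.participants
            truth_events.append(
                InteractionEvent(
                    frame_span=(lo, hi),
                    participants=(min(a, b), max(a, b)),
                    kind="animal_animal",
                    fine_label=ev.fine_label,
                )
            )
        elif ev.kind == "enrichment":
            a, name = ev.participants
            truth_events.append(
                InteractionEvent(
                    frame_span=(lo, hi), participants=(a, name), kind="enrichment"
                )
            )
        elif ev.kind == "walk":
            truth_distance[ev.participants[0]] += float(ev.distance_cm or 0.0)
        elif ev.kind == "lying":
            truth_lying[ev.participants[0]] += hi - lo + 1
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    for f in range(n_frames):
        group: list[TrackFrame] = []
        pos = homes.copy()
        posture = ["standing"] * script.n_pigs
        parts_override: dict[int, dict] = {}

        for ev in script.events:
            lo, hi = span(ev)
            if not (lo <= f <= hi):
                continue
            if ev.kind == "lying":
                posture[ev.participants[0]] = "lying"
            elif ev.kind == "walk":
                # walk along +y: the home grid leaves that band free
                a = ev.participants[0]
                frac = (f - lo) / max(1, hi - lo)
                pos[a] = homes[a] + np.array([0.0, float(ev.distance_cm) * frac])
            elif ev.kind == "enrichment":
                a, name = ev.participants
                pos[a] = fixture_world[name].copy()
            elif ev.kind == "animal_animal":
                a, b = ev.participants
                osc = _OSC_CM if (f - lo) % 2 else 0.0
                pos[a] = pos[b] + np.array([-_CONTACT_GAP_CM + osc, 0.0])

        # build track frames; animal-animal events get label-specific parts
        tfs: dict[int, TrackFrame] = {}
        for p in range(script.n_pigs):
            tfs[p] = _pig_track_frame(f, p, pos[p], posture[p], transform)
        for ev in aa_events:
            lo, hi = span(ev)
            if not (lo <= f <= hi):
                continue
            a, b = ev.participants
            contact_w = (pos[a] + pos[b]) / 2.0
            contact_px = transform.to_pixel([tuple(contact_w)])[0]
            pa, pb = _event_parts(
                ev.fine_label or "body_contact", tfs[a].bbox, tfs[b].bbox, contact_px
            )
            tfs[a] = tfs[a].model_copy(update={"parts": pa})
            tfs[b] = tfs[b].model_copy(update={"parts": pb})
        frames[f] = [tfs[p] for p in range(script.n_pigs)]

    frame_images: dict[int, np.ndarray] = {}
    if render:
        needed: set[int] = set()
        for ev in aa_events:
            lo, hi = span(ev)
            needed.update(range(max(0, lo - 1), min(n_frames, hi + 2)))
        textures = {
            p: np.random.default_rng(script.seed * 1000 + 17 + p)
            .integers(40, 220, size=(64, 64))
            .astype(np.uint8)
            for p in range(script.n_pigs)
        }
        for f in sorted(needed):
            img = np.full(_IMG_SHAPE, 30, dtype=np.uint8)
            for tf in frames[f]:
                x0, y0, x1, y1 = (int(round(v)) for v in tf.bbox)
                x0c, y0c = max(0, x0), max(0, y0)
                x1c, y1c = min(_IMG_SHAPE[1], x1), min(_IMG_SHAPE[0], y1)
                if x1c <= x0c or y1c <= y0c:
                    continue
                tex = textures[tf.animal_track_id]
                reps = ((y1c - y0c) // 64 + 1, (x1c - x0c) // 64 + 1)
                img[y0c:y1c, x0c:x1c] = np.tile(tex, reps)[: y1c - y0c, : x1c - x0c]
            frame_images[f] = img

    truth_events.sort(key=lambda e: (e.frame_span, str(e.participants)))
    return PenScene(
        frames=frames,
        frame_images=frame_images,
        truth_events=truth_events,
        truth_distance_cm=truth_distance,
        truth_lying_frames=truth_lying,
        pen=pen,
        transform=transform,
    )


def gen_occlusion_scene(
    n_frames: int = 100,
    swap_frame: int = 50,
    fps: float = PIG_FPS,
    seed: int = 0,
) -> tuple[dict[int, list[TrackFrame]], WorldTransform, dict[int, int]]:
    """Two pigs cross; the tracker loses both during a brief occlusion and
    re-emits them under new ids attached to the wrong animals.

    Returns ``(frames, transform, truth)`` where ``truth`` maps each
    emitted track id to the true pig id (0 or 1).
    """
    pen = make_pen(2, with_roster=False)
    transform = compute_world_transform(pen.corners_px, pen.world_dims)
    # true pig world paths: walk toward each other, pass, continue
    t = np.arange(n_frames, dtype=float)
    path0 = np.column_stack([100.0 + 2.0 * t, np.full(n_frames, 180.0)])
    path1 = np.column_stack([300.0 - 2.0 * t, np.full(n_frames, 184.0)])
    occluded = range(swap_frame - 2, swap_frame)  # tracker drops both pigs
    frames: dict[int, list[TrackFrame]] = {}
    truth: dict[int, int] = {0: 0, 1: 1, 100: 1, 101: 0}
    for f in range(n_frames):
        if f in occluded:
            frames[f] = []
            continue
        if f < swap_frame:
            ids = {0: path0[f], 1: path1[f]}
        else:
            # new ids, attached to the wrong pigs (a swap)
            ids = {100: path1[f], 101: path0[f]}
        frames[f] = [
            _pig_track_frame(f, pid, xy, "standing", transform)
            for pid, xy in sorted(ids.items())
        ]
    return frames, transform, truth


# ---------------------------------------------------------------------------
# Tag / mark color observations
# ---------------------------------------------------------------------------


def gen_color_observations(
    roster: Sequence[AnimalTemplate],
    sigma_lab: float,
    n: int,
    seed: int = 0,
) -> list[tuple[str, LabColor]]:
    """Draw labeled tag-color observations: Gaussian L*a*b* perturbations
    (std ``sigma_lab`` per channel) around uniformly chosen templates, with
    L* clipped to [0, 100]."""
    if not roster:
        raise ValueError("empty roster")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = roster[int(rng.integers(len(roster)))]
        L, a, b = t.lab_color
        if sigma_lab > 0:
            L = float(np.clip(L + rng.normal(0, sigma_lab), 0.0, 100.0))
            a = float(a + rng.normal(0, sigma_lab))
            b = float(b + rng.normal(0, sigma_lab))
        out.append((t.animal_id, LabColor(L, a, b)))
    return out
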