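"""Domain types shared by the cattle and pig analysis modules.

Coordinate convention throughout: image origin at the top-left corner,
x increasing rightward, y increasing downward, pixel centers at integer
coordinates. World (pen) coordinates are in centimeters after the
perspective transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import SchemaError

#: Keypoint names that every cattle pose must carry.
REQUIRED_KEYPOINTS: tuple[str, ...] = (
    "head",
    "withers",
    "pin",
    "fr_elbow",
    "fl_elbow",
    "br_elbow",
    "bl_elbow",
    "fr_hoof",
    "fl_hoof",
    "br_hoof",
    "bl_hoof",
)

#: Default names for the five non-required slots of the 16-keypoint skeleton.
#: Upstream pose models with a different ordering are bound via an alias map
#: at read time; these defaults are placeholders, not a claim about any
#: particular annotation scheme.
DEFAULT_EXTRA_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "neck",
    "spine_mid",
    "tail_base",
    "tail_tip",
)

N_KEYPOINTS = 16

PART_NAMES: frozenset[str] = frozenset({"mouth", "left_ear", "right_ear", "body", "tail"})
ENRICHMENT_NAMES: frozenset[str] = frozenset({"feeder", "drinker", "hay", "pole", "ball"})
SYMBOLS: tuple[str, ...] = ("triangle", "circle", "line", "cross")

#: Default pen dimensions in centimeters (length along x, width along y).
DEFAULT_WORLD_DIMS: tuple[float, float] = (580.0, 380.0)

#: Default acquisition frame rates (Hz): side-view cattle clips and pig pens.
CATTLE_FPS = 20.0
PIG_FPS = 15.0

Point = tuple[float, float]


class Keypoint(BaseModel):
    model_config = ConfigDict(frozen=True)

    x: float
    y: float
    confidence: float

    @field_validator("x", "y")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("keypoint coordinates must be finite")
        return v

    @field_validator("confidence")
    @classmethod
    def _unit(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"confidence {v} outside [0, 1]")
        return v


class CattlePose(BaseModel):
    """One animal's 16 named keypoints in one side-view frame (pixels)."""

    model_config = ConfigDict(frozen=True)

    frame_index: int
    keypoints: dict[str, Keypoint]

    @field_validator("frame_index")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("frame_index must be >= 0")
        return v

    @model_validator(mode="after")
    def _check_slots(self) -> "CattlePose":
        missing = [k for k in REQUIRED_KEYPOINTS if k not in self.keypoints]
        if missing:
            raise ValueError(f"missing required keypoint(s): {', '.join(missing)}")
        if len(self.keypoints) != N_KEYPOINTS:
            raise ValueError(
                f"expected exactly {N_KEYPOINTS} keypoints, got {len(self.keypoints)}"
            )
        return self


@dataclass(frozen=True)
class GaitFeatureVector:
    """Per-frame locomotion features.

    ``body_length`` is in pixels; the step sizes and hoof–elbow shifts are
    normalized by body length (dimensionless), ``head_position`` by the mean
    vertical hoof–elbow extent, and ``back_straightness`` lies in [0, 1]
    (1 = straight back, 0 = severe arching).  A feature that could not be
    computed (low-confidence keypoint, no back edge supplied) is NaN.
    """

    body_length: float
    right_step: float
    left_step: float
    head_position: float
    fr_shift: float
    fl_shift: float
    br_shift: float
    bl_shift: float
    back_straightness: float = math.nan

    #: Table column order used by feature tables (body_length first).
    FIELDS = (
        "body_length",
        "right_step",
        "left_step",
        "head_position",
        "fr_shift",
        "fl_shift",
        "br_shift",
        "bl_shift",
        "back_straightness",
    )
    #: The 8 features fed to the locomotion-score classifier (no body_length).
    LS_FIELDS = FIELDS[1:]

    def __post_init__(self) -> None:
        if not (self.body_length > 0) or not math.isfinite(self.body_length):
            raise SchemaError(f"body_length must be finite and > 0, got {self.body_length}")
        if math.isfinite(self.back_straightness) and not (0.0 <= self.back_straightness <= 1.0):
            raise SchemaError(f"back_straightness {self.back_straightness} outside [0, 1]")

    def ls_row(self) -> list[float]:
        """The 8 classifier features in canonical order."""
        return [getattr(self, f) for f in self.LS_FIELDS]


Posture = Literal["standing", "lying"]


class TrackFrame(BaseModel):
    """One pig's tracked state in one frame."""

    model_config = ConfigDict(frozen=True)

    frame_index: int
    animal_track_id: int
    bbox: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    centroid: Point
    posture: Posture
    parts: Optional[dict[str, list[Point]]] = None

    @model_validator(mode="after")
    def _check_geometry(self) -> "TrackFrame":
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        cx, cy = self.centroid
        if not (x0 <= cx <= x1 and y0 <= cy <= y1):
            raise ValueError(f"centroid {self.centroid} outside bbox {self.bbox}")
        if self.parts is not None:
            unknown = set(self.parts) - PART_NAMES
            if unknown:
                raise ValueError(f"unknown part name(s): {sorted(unknown)}")
        return self


class AnimalTemplate(BaseModel):
    """Roster entry: an animal's reference tag/mark color (CIE L*a*b*)."""

    model_config = ConfigDict(frozen=True)

    animal_id: str
    lab_color: tuple[float, float, float]
    symbol: Optional[Literal["triangle", "circle", "line", "cross"]] = None

    @field_validator("lab_color")
    @classmethod
    def _check_lab(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        L, a, b = v
        if not all(math.isfinite(c) for c in v):
            raise ValueError("lab_color must be finite")
        if not (0.0 <= L <= 100.0):
            raise ValueError(f"L* {L} outside [0, 100]")
        return v


def _collinear(p: Point, q: Point, r: Point, tol: float = 1e-9) -> bool:
    area2 = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
    scale = max(abs(c) for pt in (p, q, r) for c in pt) or 1.0
    return abs(area2) <= tol * scale * scale


class PenConfig(BaseModel):
    """Static description of one pen: corner correspondence, fixtures, roster.

    ``corners_px`` are ordered clockwise starting from the corner mapped to
    the world origin; the world rectangle has length (default 580 cm) along
    x and width (default 380 cm) along y.
    """

    model_config = ConfigDict(frozen=True)

    corners_px: tuple[Point, Point, Point, Point]
    world_dims: tuple[float, float] = DEFAULT_WORLD_DIMS
    enrichment: dict[str, list[Point]] = {}
    roster: list[AnimalTemplate] = []
    fps: float = PIG_FPS

    @model_validator(mode="after")
    def _check(self) -> "PenConfig":
        L, W = self.world_dims
        if not (L > 0 and W > 0):
            raise ValueError(f"world dimensions must be positive, got {self.world_dims}")
        c = self.corners_px
        for i in range(4):
            for j in range(i + 1, 4):
                for k in range(j + 1, 4):
                    if _collinear(c[i], c[j], c[k]):
                        raise ValueError(
                            f"pen corners {i}, {j}, {k} are collinear: {c[i]}, {c[j]}, {c[k]}"
                        )
        unknown = set(self.enrichment) - ENRICHMENT_NAMES
        if unknown:
            raise ValueError(
                f"unknown enrichment name(s) {sorted(unknown)}; "
                f"expected subset of {sorted(ENRICHMENT_NAMES)}"
            )
        return self


#: A snapshot scorer maps a cropped top-down image to a condition score in
#: [1, 5] (1 = emaciated, 5 = obese).  The scoring model itself is pluggable;
#: this package only defines the contract and clamps outputs into range.
SnapshotScorer = Callable[[object], float]


def clamp_score(value: float) -> float:
    """Clamp a snapshot-scorer output to the 1–5 condition scale."""
    return min(5.0, max(1.0, float(value)))
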