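"""Readers and writers for pose streams, track streams, and pen configuration.

The native on-disk format is JSON Lines (one record per line), which is
append-friendly for edge acquisition.  COCO-keypoints JSON is accepted for
pose import; an alias map rebinds upstream keypoint names to the canonical
skeleton.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from pydantic import ValidationError

from .errors import ConfigError, ParseError, SchemaError
from .types import (
    CattlePose,
    DEFAULT_EXTRA_KEYPOINTS,
    Keypoint,
    N_KEYPOINTS,
    PenConfig,
    REQUIRED_KEYPOINTS,
    TrackFrame,
)

logger = logging.getLogger(__name__)

CANONICAL_KEYPOINT_ORDER: tuple[str, ...] = REQUIRED_KEYPOINTS + DEFAULT_EXTRA_KEYPOINTS


def _apply_aliases(name: str, alias_map: Mapping[str, str] | None) -> str:
    if alias_map and name in alias_map:
        return alias_map[name]
    return name


def _pose_from_record(record: dict, line: int, alias_map: Mapping[str, str] | None) -> CattlePose:
    try:
        kps = {
            _apply_aliases(name, alias_map): Keypoint(
                x=float(v[0]), y=float(v[1]), confidence=float(v[2])
            )
            for name, v in record["keypoints"].items()
        }
        return CattlePose(frame_index=int(record["frame_index"]), keypoints=kps)
    except (KeyError, IndexError, TypeError) as exc:
        raise ParseError(f"malformed pose record: {exc!r}", line=line) from exc
    except (ValidationError, ValueError) as exc:
        raise SchemaError(f"line {line}: {exc}") from exc


def read_pose_stream(
    path: str | Path,
    format: str = "jsonl",
    alias_map: Mapping[str, str] | None = None,
) -> list[CattlePose]:
    """Read a pose stream, returning poses sorted by frame index.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"jsonl"`` (native) or ``"coco_json"`` (COCO keypoints export).
    alias_map:
        Optional mapping from upstream keypoint names to canonical names,
        applied before schema validation.
    """
    path = Path(path)
    if format == "jsonl":
        poses = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"invalid JSON: {exc.msg}", line=lineno) from exc
                poses.append(_pose_from_record(record, lineno, alias_map))
    elif format == "coco_json":
        poses = _read_coco_poses(path, alias_map)
    else:
        raise ValueError(f"unknown pose format {format!r}")
    poses.sort(key=lambda p: p.frame_index)
    return poses


def _read_coco_poses(path: Path, alias_map: Mapping[str, str] | None) -> list[CattlePose]:
    with path.open() as fh:
        doc = json.load(fh)
    try:
        names = [
            _apply_aliases(n, alias_map) for n in doc["categories"][0]["keypoints"]
        ]
    except (KeyError, IndexError) as exc:
        raise ParseError("COCO document lacks categories[0].keypoints") from exc
    if len(names) != N_KEYPOINTS:
        raise SchemaError(
            f"COCO skeleton has {len(names)} keypoints; expected {N_KEYPOINTS}"
        )
    image_frame = {
        img["id"]: int(img.get("frame_index", img["id"])) for img in doc.get("images", [])
    }
    poses = []
    for ann in doc.get("annotations", []):
        flat = ann["keypoints"]
        kps = {}
        for i, name in enumerate(names):
            x, y, v = flat[3 * i : 3 * i + 3]
            # COCO visibility: 0 unlabeled, 1 occluded, 2 visible.
            conf = {0: 0.0, 1: 0.5, 2: 1.0}.get(int(v), 0.0)
            kps[name] = Keypoint(x=float(x), y=float(y), confidence=conf)
        frame = image_frame.get(ann.get("image_id"), ann.get("image_id", 0))
        try:
            poses.append(CattlePose(frame_index=frame, keypoints=kps))
        except ValidationError as exc:
            raise SchemaError(f"annotation for image {ann.get('image_id')}: {exc}") from exc
    return poses


def write_pose_stream(poses: Iterable[CattlePose], path: str | Path) -> None:
    """Write poses as canonical JSON Lines (keypoints in canonical order)."""
    with Path(path).open("w") as fh:
        for pose in poses:
            ordered = {
                name: [kp.x, kp.y, kp.confidence]
                for name, kp in sorted(
                    pose.keypoints.items(),
                    key=lambda kv: (
                        CANONICAL_KEYPOINT_ORDER.index(kv[0])
                        if kv[0] in CANONICAL_KEYPOINT_ORDER
                        else N_KEYPOINTS
                    ),
                )
            }
            fh.write(
                json.dumps({"frame_index": pose.frame_index, "keypoints": ordered}) + "\n"
            )


def read_back_edges(path: str | Path) -> dict[int, "BackEdge"]:
    """Read a back-silhouette edge stream (JSON Lines) keyed by frame.

    Records: ``{"frame_index": i, "body_length_ref": L, "points": [[x, y], ...]}``.
    """
    from .gait import BackEdge

    edges: dict[int, BackEdge] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc.msg}", line=lineno) from exc
            try:
                edges[int(rec["frame_index"])] = BackEdge(
                    points=rec["points"], body_length_ref=float(rec["body_length_ref"])
                )
            except (KeyError, TypeError) as exc:
                raise ParseError(f"malformed edge record: {exc!r}", line=lineno) from exc
    return edges


def write_back_edges(edges: Mapping[int, "BackEdge"], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for fidx in sorted(edges):
            e = edges[fidx]
            fh.write(
                json.dumps(
                    {
                        "frame_index": fidx,
                        "body_length_ref": e.body_length_ref,
                        "points": np.asarray(e.points).tolist(),
                    }
                )
                + "\n"
            )


def read_track_stream(path: str | Path) -> dict[int, list[TrackFrame]]:
    """Read a JSON Lines track stream, grouped and ordered by frame index.

    Per-track frame-contiguity gaps are reported as warnings, not errors:
    trackers legitimately drop animals during occlusions.
    """
    path = Path(path)
    frames: dict[int, list[TrackFrame]] = {}
    last_seen: dict[int, int] = {}
    n = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc.msg}", line=lineno) from exc
            try:
                tf = TrackFrame(**record)
            except ValidationError as exc:
                raise SchemaError(f"line {lineno}: {exc}") from exc
            frames.setdefault(tf.frame_index, []).append(tf)
            prev = last_seen.get(tf.animal_track_id)
            if prev is not None and tf.frame_index > prev + 1:
                logger.warning(
                    "track %d has a gap: frames %d -> %d",
                    tf.animal_track_id,
                    prev,
                    tf.frame_index,
                )
            last_seen[tf.animal_track_id] = max(
                tf.frame_index, last_seen.get(tf.animal_track_id, tf.frame_index)
            )
            n += 1
    if n == 0:
        logger.warning("track stream %s is empty", path)
    return dict(sorted(frames.items()))


def write_track_stream(
    frames: Mapping[int, Sequence[TrackFrame]] | Iterable[TrackFrame], path: str | Path
) -> None:
    """Write track frames as JSON Lines ordered by (frame, track id)."""
    if isinstance(frames, Mapping):
        flat = [tf for _, group in sorted(frames.items()) for tf in group]
    else:
        flat = sorted(frames, key=lambda tf: (tf.frame_index, tf.animal_track_id))
    with Path(path).open("w") as fh:
        for tf in flat:
            fh.write(json.dumps(tf.model_dump(), default=list) + "\n")


def load_pen_config(path: str | Path) -> PenConfig:
    """Load and validate a pen configuration from YAML or JSON."""
    path = Path(path)
    with path.open() as fh:
        if path.suffix.lower() == ".json":
            doc = json.load(fh)
        else:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: pen config must be a mapping")
    if "roster" in doc:
        doc = dict(doc)
        doc["roster"] = [_roster_entry(e) for e in doc["roster"]]
    try:
        return PenConfig(**doc)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _roster_entry(entry: dict) -> dict:
    """Normalize a roster entry; an ``rgb`` color is converted to L*a*b*."""
    entry = dict(entry)
    if "rgb" in entry and "lab" not in entry and "lab_color" not in entry:
        from .colorid import rgb_to_lab

        entry["lab_color"] = tuple(rgb_to_lab(tuple(entry.pop("rgb"))))
    elif "lab" in entry:
        entry["lab_color"] = tuple(entry.pop("lab"))
    if "id" in entry and "animal_id" not in entry:
        entry["animal_id"] = entry.pop("id")
    return entry
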