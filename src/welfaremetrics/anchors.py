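"""Open-set markerless identification via centroid anchors.

A pluggable encoder projects animal images into a low-dimensional metric
space (3-D by default).  Each known animal is represented by an anchor —
the center of mass of its training encodings.  A query is assigned to the
nearest anchor by Euclidean distance, or rejected when no anchor lies
within a configured threshold (signaling a poor acquisition or a new
animal).  New animals are enrolled by adding anchors; existing anchors are
refined as running means — no retraining of the encoder is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import SchemaError


class _Rejected:
    """Sentinel for a query rejected by the open-set threshold."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "REJECTED"

    def __bool__(self) -> bool:
        return False


REJECTED = _Rejected()

DEFAULT_DIM = 3


@dataclass(frozen=True)
class AnchorDictionary:
    """Anchors (one per known animal), counts, and the rejection threshold."""

    anchors: dict[str, np.ndarray]
    threshold: float
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise SchemaError(f"threshold must be > 0, got {self.threshold}")
        dims = {np.asarray(a).shape for a in self.anchors.values()}
        if len(dims) > 1:
            raise SchemaError(f"anchors have inconsistent dimensions: {dims}")
        for aid, a in self.anchors.items():
            arr = np.asarray(a, dtype=float)
            if arr.ndim != 1 or not np.all(np.isfinite(arr)):
                raise SchemaError(f"anchor for {aid!r} must be a finite vector")
            self.anchors[aid] = arr
        for aid, c in self.counts.items():
            if c < 1:
                raise SchemaError(f"count for {aid!r} must be >= 1, got {c}")
        if set(self.counts) != set(self.anchors):
            raise SchemaError("counts and anchors must cover the same animal ids")

    @property
    def dim(self) -> int:
        return next(iter(self.anchors.values())).shape[0]

    def __len__(self) -> int:
        return len(self.anchors)


def _as_points(encodings: Sequence, animal_id: str) -> np.ndarray:
    pts = np.asarray(encodings, dtype=float)
    if pts.size == 0:
        raise SchemaError(f"empty encoding list for animal {animal_id!r}")
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2:
        raise SchemaError(f"encodings for {animal_id!r} must be a list of points")
    return pts


def build_anchor_dictionary(
    encodings: Mapping[str, Sequence], threshold: float
) -> AnchorDictionary:
    """Build anchors as the per-animal center of mass of training encodings."""
    if not encodings:
        raise SchemaError("no encodings supplied")
    anchors: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    dim: int | None = None
    for aid, enc in encodings.items():
        pts = _as_points(enc, aid)
        if dim is None:
            dim = pts.shape[1]
        elif pts.shape[1] != dim:
            raise SchemaError(
                f"encoding dimension mismatch: {aid!r} has {pts.shape[1]}, expected {dim}"
            )
        anchors[aid] = pts.mean(axis=0)
        counts[aid] = len(pts)
    return AnchorDictionary(anchors=anchors, threshold=float(threshold), counts=counts)


def identify(
    query: Sequence[float], dictionary: AnchorDictionary
) -> tuple[str | _Rejected, float]:
    """Assign a query encoding to the nearest anchor, or reject it.

    Returns ``(animal_id, distance)`` for the Euclidean-nearest anchor when
    that distance is within the threshold, else ``(REJECTED, min_distance)``.
    Exact distance ties resolve to the lexicographically smallest id.
    """
    if len(dictionary) == 0:
        raise SchemaError("anchor dictionary is empty")
    q = np.asarray(query, dtype=float)
    if q.shape != (dictionary.dim,):
        raise SchemaError(
            f"query dimension {q.shape} does not match anchors ({dictionary.dim},)"
        )
    ids = sorted(dictionary.anchors)
    dists = np.array([np.linalg.norm(q - dictionary.anchors[i]) for i in ids])
    best = int(np.argmin(dists))  # argmin takes the first = smallest id on ties
    d = float(dists[best])
    if d <= dictionary.threshold:
        return ids[best], d
    return REJECTED, d


def enroll(
    dictionary: AnchorDictionary, animal_id: str, encodings: Sequence
) -> AnchorDictionary:
    """Return a new dictionary with ``animal_id`` enrolled or refined.

    A new id gets an anchor at the mean of its encodings; an existing id's
    anchor becomes the running mean over all encodings seen so far.  All
    other anchors are untouched.
    """
    pts = _as_points(encodings, animal_id)
    if len(dictionary) and pts.shape[1] != dictionary.dim:
        raise SchemaError(
            f"encoding dimension {pts.shape[1]} does not match dictionary ({dictionary.dim})"
        )
    anchors = {aid: a.copy() for aid, a in dictionary.anchors.items()}
    counts = dict(dictionary.counts)
    if animal_id in anchors:
        n_old = counts[animal_id]
        n_new = len(pts)
        anchors[animal_id] = (n_old * anchors[animal_id] + pts.sum(axis=0)) / (
            n_old + n_new
        )
        counts[animal_id] = n_old + n_new
    else:
        anchors[animal_id] = pts.mean(axis=0)
        counts[animal_id] = len(pts)
    return AnchorDictionary(anchors=anchors, threshold=dictionary.threshold, counts=counts)


def derive_threshold(
    encodings: Mapping[str, Sequence], quantile: float = 0.99
) -> float:
    """Derive an open-set rejection threshold from labeled training encodings.

    The threshold is the ``quantile`` of within-cluster anchor distances,
    capped at half the minimum inter-anchor distance.  The cap makes
    accepted assignments unambiguous: when a query lies within the
    threshold of its own anchor, the triangle inequality puts every other
    anchor at least as far away, so the nearest-anchor rule cannot pick a
    wrong identity for it.
    """
    d = build_anchor_dictionary(encodings, threshold=np.inf)
    within = [
        float(np.linalg.norm(np.asarray(p, dtype=float) - d.anchors[aid]))
        for aid, pts in encodings.items()
        for p in np.atleast_2d(np.asarray(pts, dtype=float))
    ]
    ids = sorted(d.anchors)
    if len(ids) < 2:
        raise SchemaError("threshold derivation needs at least 2 identities")
    min_sep = min(
        np.linalg.norm(d.anchors[a] - d.anchors[b])
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    )
    thr = min(float(np.quantile(within, quantile)), float(min_sep) / 2.0)
    if thr <= 0:
        raise SchemaError("derived threshold is not positive (degenerate clusters)")
    return thr


def save_anchor_dictionary(dictionary: AnchorDictionary, path: str | Path) -> None:
    doc = {
        "dim": dictionary.dim,
        "threshold": dictionary.threshold,
        "anchors": {aid: a.tolist() for aid, a in sorted(dictionary.anchors.items())},
        "counts": {aid: int(c) for aid, c in sorted(dictionary.counts.items())},
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_anchor_dictionary(path: str | Path) -> AnchorDictionary:
    doc = json.loads(Path(path).read_text())
    d = AnchorDictionary(
        anchors={aid: np.asarray(a, dtype=float) for aid, a in doc["anchors"].items()},
        threshold=float(doc["threshold"]),
        counts={aid: int(c) for aid, c in doc["counts"].items()},
    )
    if d.dim != int(doc["dim"]):
        raise SchemaError(f"declared dim {doc['dim']} does not match anchors ({d.dim})")
    return d
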