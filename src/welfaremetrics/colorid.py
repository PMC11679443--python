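"""Pig identification from ear-tag / livestock-mark color.

The mean RGB over the detected tag or mark region is converted to CIE
L*a*b* (sRGB decoding, D65 white) and compared against user-defined
per-animal templates with the CIEDE2000 color-difference formula; when a
mark symbol (triangle / circle / line / cross) is available it restricts
the candidate set before color matching.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import ConfigError, SchemaError
from .types import AnimalTemplate, SYMBOLS


class LabColor(NamedTuple):
    """CIE 1976 L*a*b* color (L in [0, 100], a/b signed)."""

    L: float
    a: float
    b: float


class _Unidentified:
    """Sentinel for an observation rejected by the color-match threshold."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "UNIDENTIFIED"

    def __bool__(self) -> bool:
        return False


UNIDENTIFIED = _Unidentified()

DEFAULT_REJECT_DELTA_E = 25.0

# sRGB (D65) linear RGB -> XYZ, IEC 61966-2-1 primaries.
_RGB_TO_XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883])


def mean_rgb(
    image: np.ndarray, mask: np.ndarray | Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """Channel-wise mean RGB over a masked region of an (H, W, 3) image.

    ``mask`` is either a boolean array of shape (H, W) or a polygon given
    as (x, y) pixel vertices, rasterized with scikit-image.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise SchemaError(f"image must be (H, W, 3), got {image.shape}")
    mask = np.asarray(mask)
    if mask.dtype != bool:
        from skimage.draw import polygon as draw_polygon

        verts = np.asarray(mask, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise SchemaError("polygon mask must be a sequence of (x, y) vertices")
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=image.shape[:2])
        m = np.zeros(image.shape[:2], dtype=bool)
        m[rr, cc] = True
        mask = m
    if mask.shape != image.shape[:2]:
        raise SchemaError("mask shape does not match image")
    if not mask.any():
        raise SchemaError("mask selects no pixels")
    r, g, b = image[mask].mean(axis=0)
    return float(r), float(g), float(b)


def rgb_to_lab(rgb: Sequence[float]) -> LabColor:
    """Convert an sRGB color (channels in [0, 255]) to CIE L*a*b* (D65).

    Applies the IEC 61966-2-1 inverse transfer function, the sRGB
    RGB-to-XYZ matrix, and the CIE 1976 L*a*b* transform with the D65
    reference white.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise SchemaError(f"rgb must be 3 channels, got shape {rgb.shape}")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise SchemaError(f"rgb channels must lie in [0, 255], got {tuple(rgb)}")
    c = rgb / 255.0
    linear = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = _RGB_TO_XYZ @ linear
    t = xyz / _D65_WHITE
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[1] - 16.0
    a = 500.0 * (f[0] - f[1])
    b = 200.0 * (f[1] - f[2])
    return LabColor(float(L), float(a), float(b))


def ciede2000(
    c1: LabColor | Sequence[float],
    c2: LabColor | Sequence[float],
    kL: float = 1.0,
    kC: float = 1.0,
    kH: float = 1.0,
) -> float:
    """CIEDE2000 color difference between two L*a*b* colors.

    Full formulation: G chroma correction, a' rescaling, the SL/SC/SH
    weighting functions, and the RT hue-rotation term for the blue region.
    """
    L1, a1, b1 = (float(v) for v in c1)
    L2, a2, b2 = (float(v) for v in c2)

    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - math.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1.0 + G) * a1, (1.0 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)

    def hp(ap: float, b: float) -> float:
        if ap == 0.0 and b == 0.0:
            return 0.0
        h = math.degrees(math.atan2(b, ap))
        return h + 360.0 if h < 0 else h

    h1p, h2p = hp(a1p, b1), hp(a2p, b2)

    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        dh = h2p - h1p
        if dh > 180.0:
            dh -= 360.0
        elif dh < -180.0:
            dh += 360.0
        dhp = dh
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0.0:
        hbp = h1p + h2p
    else:
        s = h1p + h2p
        if abs(h1p - h2p) <= 180.0:
            hbp = 0.5 * s
        elif s < 360.0:
            hbp = 0.5 * (s + 360.0)
        else:
            hbp = 0.5 * (s - 360.0)

    T = (
        1.0
        - 0.17 * math.cos(math.radians(hbp - 30.0))
        + 0.24 * math.cos(math.radians(2.0 * hbp))
        + 0.32 * math.cos(math.radians(3.0 * hbp + 6.0))
        - 0.20 * math.cos(math.radians(4.0 * hbp - 63.0))
    )
    d_theta = 30.0 * math.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * math.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / math.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -math.sin(math.radians(2.0 * d_theta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return math.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)


def match_template(
    observed: LabColor | Sequence[float],
    roster: Sequence[AnimalTemplate],
    symbol: Optional[str] = None,
    reject_threshold: float = DEFAULT_REJECT_DELTA_E,
) -> tuple[str | _Unidentified, float]:
    """Match an observed tag/mark color against the pen roster.

    With a ``symbol`` (livestock-mark mode) the candidate set is restricted
    to roster entries carrying that symbol; without one (ear-tag mode) all
    entries compete.  Returns the id minimizing CIEDE2000 if the minimum is
    within ``reject_threshold``, else ``(UNIDENTIFIED, min_delta_e)``.
    Exact ties resolve to the smallest animal id.
    """
    if not roster:
        raise ConfigError("empty roster")
    if symbol is not None:
        if symbol not in SYMBOLS:
            raise ConfigError(f"unknown symbol {symbol!r}; expected one of {SYMBOLS}")
        if all(t.symbol is None for t in roster):
            raise ConfigError(
                "symbol given but no roster entry carries a symbol"
            )
        candidates = [t for t in roster if t.symbol == symbol]
        if not candidates:
            return UNIDENTIFIED, math.inf
    else:
        candidates = list(roster)
    candidates = sorted(candidates, key=lambda t: t.animal_id)
    deltas = [ciede2000(observed, t.lab_color) for t in candidates]
    best = int(np.argmin(deltas))  # first minimum = smallest id on ties
    if deltas[best] <= reject_threshold:
        return candidates[best].animal_id, float(deltas[best])
    return UNIDENTIFIED, float(deltas[best])
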