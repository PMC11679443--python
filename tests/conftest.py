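import numpy as np
import pytest

from welfaremetrics.types import (
    CattlePose,
    DEFAULT_EXTRA_KEYPOINTS,
    Keypoint,
    REQUIRED_KEYPOINTS,
)

#: Default side-view skeleton (pixels): cow facing +x, hooves below elbows.
DEFAULT_SKELETON = {
    "head": (420.0, 140.0),
    "withers": (300.0, 200.0),
    "pin": (100.0, 200.0),
    "fr_elbow": (290.0, 300.0),
    "fl_elbow": (280.0, 300.0),
    "br_elbow": (110.0, 300.0),
    "bl_elbow": (120.0, 300.0),
    "fr_hoof": (290.0, 380.0),
    "fl_hoof": (280.0, 380.0),
    "br_hoof": (110.0, 380.0),
    "bl_hoof": (120.0, 380.0),
    "nose": (450.0, 150.0),
    "neck": (340.0, 180.0),
    "spine_mid": (200.0, 195.0),
    "tail_base": (90.0, 210.0),
    "tail_tip": (80.0, 300.0),
}


def make_pose(frame_index: int = 0, confidence: float = 1.0, **overrides) -> CattlePose:
    """Build a valid 16-keypoint pose from the default skeleton.

    Overrides are keypoint name -> (x, y) or (x, y, confidence).
    """
    kps = {}
    for name, (x, y) in DEFAULT_SKELETON.items():
        conf = confidence
        if name in overrides:
            o = overrides[name]
            x, y = o[0], o[1]
            if len(o) == 3:
                conf = o[2]
        kps[name] = Keypoint(x=x, y=y, confidence=conf)
    return CattlePose(frame_index=frame_index, keypoints=kps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pen():
    from welfaremetrics.synth import make_pen

    return make_pen(4)
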