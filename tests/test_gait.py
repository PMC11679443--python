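"""Gait feature formulas, back straightness, windowing, and scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from welfaremetrics.errors import (
    DegeneratePoseError,
    DegenerateTrainingError,
    InsufficientEdgeError,
)
from welfaremetrics.gait import (
    BackEdge,
    back_straightness_score,
    build_windows,
    extract_gait_features,
    feature_matrix,
    infer_walking_direction,
    score_clip,
    train_sequence_classifier,
)
from welfaremetrics.synth import GaitScript, gen_gait_sequence

from conftest import make_pose


class TestFeatureFormulas:
    def test_body_length_is_withers_pin_distance(self):
        fv = extract_gait_features(make_pose(withers=(0, 100), pin=(100, 100)))
        assert fv.body_length == pytest.approx(100.0)

    def test_hoof_below_elbow_gives_zero_shifts(self):
        fv = extract_gait_features(make_pose())
        assert (fv.fr_shift, fv.fl_shift, fv.br_shift, fv.bl_shift) == (0, 0, 0, 0)

    def test_right_step_normalized_by_body_length(self):
        fv = extract_gait_features(
            make_pose(withers=(0, 100), pin=(100, 100), fr_hoof=(120, 380), br_hoof=(40, 380))
        )
        assert fv.right_step == pytest.approx(0.8)

    def test_head_position_uses_ground_line_and_leg_height(self):
        # hooves at y=380, elbows at y=300 -> leg height 80; head at y=140
        fv = extract_gait_features(make_pose())
        assert fv.head_position == pytest.approx((380 - 140) / 80)

    def test_shift_sign_flips_with_walking_direction(self):
        pose = make_pose(fr_hoof=(280.0, 380.0))  # hoof 10 px behind elbow
        f_right = extract_gait_features(pose, walking_direction_sign=1)
        f_left = extract_gait_features(pose, walking_direction_sign=-1)
        assert f_right.fr_shift == pytest.approx(-f_left.fr_shift)
        assert f_right.fr_shift != 0

    def test_low_confidence_keypoint_marks_feature_missing(self):
        fv = extract_gait_features(make_pose(fr_hoof=(290, 380, 0.1)))
        assert math.isnan(fv.right_step) and math.isnan(fv.fr_shift)
        assert math.isfinite(fv.left_step)

    def test_degenerate_body_length_raises(self):
        with pytest.raises(DegeneratePoseError):
            extract_gait_features(make_pose(withers=(100, 100), pin=(100, 100)))

    def test_back_straightness_absent_without_edge(self):
        assert math.isnan(extract_gait_features(make_pose()).back_straightness)

    def test_translation_invariance(self):
        base = extract_gait_features(make_pose())
        shifted = make_pose(
            **{
                n: (kp.x + 37.0, kp.y - 12.5)
                for n, kp in make_pose().keypoints.items()
            }
        )
        moved = extract_gait_features(shifted)
        for f in base.LS_FIELDS[:-1]:  # back_straightness not pose-derived
            assert getattr(moved, f) == pytest.approx(getattr(base, f), abs=1e-12)

    @pytest.mark.parametrize("s", [0.5, 2.0, 3.0])
    def test_scale_invariance(self, s):
        base = extract_gait_features(make_pose())
        scaled_pose = make_pose(
            **{n: (kp.x * s, kp.y * s) for n, kp in make_pose().keypoints.items()}
        )
        scaled = extract_gait_features(scaled_pose)
        assert scaled.body_length == pytest.approx(base.body_length * s)
        for f in base.LS_FIELDS[:-1]:
            assert getattr(scaled, f) == pytest.approx(getattr(base, f), abs=1e-12)


def _arc_edge(sagitta: float, body_length: float = 200.0, n: int = 21) -> BackEdge:
    t = np.linspace(0.0, 1.0, n)
    x = t * body_length
    y = 100.0 - sagitta * 4.0 * t * (1.0 - t)
    return BackEdge(points=np.column_stack([x, y]), body_length_ref=body_length)


class TestBackStraightness:
    def test_collinear_points_score_one(self):
        assert back_straightness_score(_arc_edge(0.0)) == pytest.approx(1.0)

    def test_deeper_arch_scores_lower(self):
        s_shallow = back_straightness_score(_arc_edge(0.1 * 200))
        s_deep = back_straightness_score(_arc_edge(0.3 * 200))
        assert s_deep < s_shallow < 1.0

    def test_strictly_decreasing_over_sagitta_grid(self):
        scores = [
            back_straightness_score(_arc_edge(f * 200.0))
            for f in np.linspace(0.0, 0.5, 11)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_invariant_to_uniform_scaling(self):
        e = _arc_edge(30.0)
        e3 = BackEdge(points=e.points * 3.0, body_length_ref=e.body_length_ref * 3.0)
        assert back_straightness_score(e3) == pytest.approx(back_straightness_score(e))

    def test_invariant_to_rigid_motion(self):
        e = _arc_edge(30.0)
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = BackEdge(
            points=e.points @ R.T + np.array([50.0, -20.0]),
            body_length_ref=e.body_length_ref,
        )
        assert back_straightness_score(moved) == pytest.approx(
            back_straightness_score(e)
        )

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientEdgeError):
            BackEdge(points=np.zeros((4, 2)), body_length_ref=100.0)


class TestBuildWindows:
    @pytest.mark.parametrize(
        "n,window,stride,expected",
        [(100, 20, 5, 17), (10, 20, 5, 0), (25, 20, 1, 6), (20, 20, 5, 1)],
    )
    def test_window_count_formula(self, n, window, stride, expected):
        rows = np.zeros((n, 8))
        assert len(build_windows(rows, window, stride)) == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(0, 200),
        window=st.integers(2, 50),
        stride=st.integers(1, 10),
    )
    def test_window_count_formula_property(self, n, window, stride):
        rows = np.zeros((n, 8))
        got = len(build_windows(rows, window, stride))
        expected = (n - window) // stride + 1 if n >= window else 0
        assert got == expected

    def test_short_gap_interpolated(self):
        rows = np.tile(np.arange(30, dtype=float)[:, None], (1, 8))
        rows[10:12] = np.nan  # 2-frame gap, bridgeable
        ws = build_windows(rows, window=30, stride=1)
        assert len(ws) == 1
        assert ws[0].features[10, 0] == pytest.approx(10.0)

    def test_long_gap_splits_sequence(self):
        rows = np.zeros((50, 8))
        rows[20:25] = np.nan  # 5-frame gap > max_gap=3
        ws = build_windows(rows, window=10, stride=10)
        starts = [w.start_frame for w in ws]
        assert starts == [0, 10, 25, 35]

    def test_windows_carry_start_frames(self):
        ws = build_windows(np.zeros((25, 8)), window=20, stride=5)
        assert [w.start_frame for w in ws] == [0, 5]


class TestClassifierAndClipScore:
    @staticmethod
    def _labeled_windows(levels, n_clips, seed0):
        windows, labels = [], []
        for lvl in levels:
            for c in range(n_clips):
                poses, edges, _ = gen_gait_sequence(
                    GaitScript(
                        lameness_level=lvl,
                        n_frames=60,
                        noise_px=1.0,
                        seed=seed0 + 100 * lvl + c,
                    )
                )
                rows = feature_matrix(
                    [
                        extract_gait_features(p, 1, back_edge=e)
                        for p, e in zip(poses, edges)
                    ]
                )
                ws = build_windows(rows, window=20, stride=10)
                windows.extend(ws)
                labels.extend([lvl] * len(ws))
        return windows, labels

    def test_two_separated_classes_high_holdout_accuracy(self):
        windows, labels = self._labeled_windows([1, 5], n_clips=10, seed0=7)
        labels = np.array(labels)
        idx = np.arange(len(windows))
        train, test = idx[::2], idx[1::2]
        clf = train_sequence_classifier(
            [windows[i] for i in train], labels[train], seed=0
        )
        pred = clf.predict_class([windows[i] for i in test])
        assert (pred == labels[test]).mean() > 0.9

    def test_same_seed_identical_predictions(self):
        windows, labels = self._labeled_windows([1, 3], n_clips=4, seed0=11)
        a = train_sequence_classifier(windows, labels, seed=5).score_windows(windows)
        b = train_sequence_classifier(windows, labels, seed=5).score_windows(windows)
        np.testing.assert_array_equal(a, b)

    def test_single_class_training_raises(self):
        windows, _ = self._labeled_windows([2], n_clips=2, seed0=3)
        with pytest.raises(DegenerateTrainingError):
            train_sequence_classifier(windows, [2] * len(windows), seed=0)

    def test_clip_score_is_mean(self):
        assert score_clip([2, 2, 3]).clip_score == pytest.approx(7 / 3)
        assert score_clip([4]).clip_score == 4.0

    def test_empty_clip_raises(self):
        with pytest.raises(ValueError):
            score_clip([])


def test_walking_direction_from_withers_displacement():
    poses, _, _ = gen_gait_sequence(GaitScript(lameness_level=1, n_frames=10))
    assert infer_walking_direction(poses) == 1
    mirrored = [
        make_pose(frame_index=i, withers=(1000 - 3 * i, 200)) for i in range(10)
    ]
    assert infer_walking_direction(mirrored) == -1
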