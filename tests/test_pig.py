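"""Pen geometry, activity accounting, and interaction rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from welfaremetrics.errors import DegenerateGeometryError, SchemaError
from welfaremetrics.pig import (
    InteractionEvent,
    build_activity_report,
    classify_fine_interaction,
    compute_world_transform,
    confirm_interaction,
    detect_contact,
    detect_enrichment_interaction,
    distance_traveled,
    part_iou,
    posture_budget,
    reassign_after_occlusion,
    track_to_world,
)
from welfaremetrics.synth import gen_occlusion_scene, make_pen
from welfaremetrics.types import TrackFrame


def _random_quad(rng):
    """A well-conditioned random convex quadrilateral (pixels)."""
    while True:
        base = np.array([(0, 0), (600, 0), (600, 450), (0, 450)], dtype=float)
        quad = base + rng.uniform(-80, 80, size=(4, 2))
        p = Polygon(quad)
        if p.is_valid and p.area > 5e4 and p.equals(p.convex_hull):
            return quad


class TestWorldTransform:
    def test_identity_when_corners_equal_world(self):
        wt = compute_world_transform(
            [(0, 0), (580, 0), (580, 380), (0, 380)], (580, 380)
        )
        H = wt.H / wt.H[2, 2]
        np.testing.assert_allclose(H, np.eye(3), atol=1e-9)

    def test_corners_map_exactly(self, rng):
        quad = _random_quad(rng)
        wt = compute_world_transform(quad, (580, 380))
        world = wt.to_world(quad)
        np.testing.assert_allclose(
            world, [(0, 0), (580, 0), (580, 380), (0, 380)], atol=1e-6
        )

    def test_round_trip_on_random_quadrilaterals(self, rng):
        for _ in range(100):
            quad = _random_quad(rng)
            wt = compute_world_transform(quad, (580, 380))
            np.testing.assert_allclose(
                wt.to_world(quad), [(0, 0), (580, 0), (580, 380), (0, 380)], atol=1e-6
            )
            pts = rng.uniform(0, 600, size=(20, 2))
            np.testing.assert_allclose(wt.to_pixel(wt.to_world(pts)), pts, atol=1e-6)

    def test_collinear_corners_raise(self):
        with pytest.raises(DegenerateGeometryError):
            compute_world_transform([(0, 0), (10, 0), (20, 0), (5, 5)], (580, 380))


def _tf(frame, tid, cx, cy, posture="standing", half=10.0):
    return TrackFrame(
        frame_index=frame,
        animal_track_id=tid,
        bbox=(cx - half, cy - half, cx + half, cy + half),
        centroid=(cx, cy),
        posture=posture,
    )


class TestTrackToWorld:
    def test_pen_center_maps_to_world_center(self):
        wt = compute_world_transform(
            [(0, 0), (580, 0), (580, 380), (0, 380)], (580, 380)
        )
        world, outside = track_to_world([_tf(0, 1, 290, 190)], wt, (580, 380))
        np.testing.assert_allclose(world[0], (290, 190), atol=1e-9)
        assert not outside.any()

    def test_far_point_flagged_outside_margin(self):
        wt = compute_world_transform(
            [(0, 0), (580, 0), (580, 380), (0, 380)], (580, 380)
        )
        _, outside = track_to_world([_tf(0, 1, 1000, 190)], wt, (580, 380))
        assert outside.all()


class TestDistanceAndPosture:
    def test_stationary_pig_travels_zero(self):
        world = np.tile([(100.0, 100.0)], (100, 1))
        res = distance_traveled(world, ["standing"] * 100, fps=15)
        assert res.distance_cm == 0.0

    def test_straight_standing_walk_sums_steps(self):
        world = np.column_stack([np.linspace(0, 100, 51), np.zeros(51)])
        res = distance_traveled(world, ["standing"] * 51, fps=15)
        assert res.distance_cm == pytest.approx(100.0)

    def test_lying_pig_accumulates_nothing(self):
        world = np.column_stack([np.linspace(0, 100, 51), np.zeros(51)])
        res = distance_traveled(world, ["lying"] * 51, fps=15)
        assert res.distance_cm == 0.0

    def test_glitch_steps_dropped_and_counted(self):
        world = np.array([(0, 0), (1, 0), (500, 0), (501, 0)], dtype=float)
        res = distance_traveled(world, ["standing"] * 4, fps=15, max_speed_cm_s=300)
        assert res.distance_cm == pytest.approx(2.0)
        assert res.dropped_steps == 1

    def test_additive_over_splits(self, rng):
        world = rng.uniform(0, 50, size=(60, 2))
        postures = ["standing"] * 60
        whole = distance_traveled(world, postures, fps=15).distance_cm
        a = distance_traveled(world[:30], postures[:30], fps=15).distance_cm
        b = distance_traveled(world[29:], postures[29:], fps=15).distance_cm
        assert whole == pytest.approx(a + b)

    def test_invariant_to_world_rotation(self, rng):
        world = rng.uniform(0, 50, size=(40, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        postures = ["standing", "lying"] * 20
        d0 = distance_traveled(world, postures, fps=15).distance_cm
        d1 = distance_traveled(world @ R.T, postures, fps=15).distance_cm
        assert d1 == pytest.approx(d0)

    def test_posture_budget_examples(self):
        assert posture_budget(["standing"] * 150, fps=15) == (10.0, 0.0)
        assert posture_budget(["standing", "lying"] * 50, fps=10) == (5.0, 5.0)
        assert posture_budget([], fps=15) == (0.0, 0.0)

    def test_budget_sums_to_duration(self, rng):
        postures = list(rng.choice(["standing", "lying"], size=333))
        s, l = posture_budget(postures, fps=15)
        assert s + l == pytest.approx(333 / 15)


class TestOcclusionReassignment:
    def test_scripted_swap_restored(self):
        frames, wt, truth = gen_occlusion_scene(n_frames=100, swap_frame=50)
        fixed, mapping = reassign_after_occlusion(frames, wt)
        assert mapping == {100: truth[100], 101: truth[101]}
        for f, group in fixed.items():
            for tf in group:
                assert tf.animal_track_id in (0, 1)

    def test_no_disappearance_is_identity(self):
        wt = compute_world_transform(
            [(0, 0), (580, 0), (580, 380), (0, 380)], (580, 380)
        )
        frames = {f: [_tf(f, 1, 100 + f, 100), _tf(f, 2, 300, 300)] for f in range(20)}
        fixed, mapping = reassign_after_occlusion(frames, wt)
        assert mapping == {}
        assert fixed == {f: list(v) for f, v in frames.items()}

    def test_new_id_beyond_gate_kept(self):
        wt = compute_world_transform(
            [(0, 0), (580, 0), (580, 380), (0, 380)], (580, 380)
        )
        frames = {f: [_tf(f, 1, 100, 100)] for f in range(10)}
        frames.update({f: [_tf(f, 7, 500, 300)] for f in range(10, 20)})
        fixed, mapping = reassign_after_occlusion(frames, wt, gate_cm=50)
        assert mapping == {}
        assert {tf.animal_track_id for tf in fixed[15]} == {7}


class TestDetectContact:
    def test_identical_boxes_full_overlap(self):
        assert detect_contact((0, 0, 10, 10), (0, 0, 10, 10)) == (True, 1.0)

    def test_disjoint_boxes_no_contact(self):
        assert detect_contact((0, 0, 10, 10), (20, 20, 30, 30)) == (False, 0.0)

    def test_half_overlap_fraction(self):
        contact, frac = detect_contact((0, 0, 10, 10), (5, 0, 15, 10))
        assert contact and frac == pytest.approx(0.5)

    def test_zero_area_bbox_raises(self):
        with pytest.raises(SchemaError):
            detect_contact((0, 0, 0, 10), (0, 0, 10, 10))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_symmetric_and_bounded(self, data):
        def box(d):
            x0 = d.draw(st.floats(0, 100))
            y0 = d.draw(st.floats(0, 100))
            w = d.draw(st.floats(1, 50))
            h = d.draw(st.floats(1, 50))
            return (x0, y0, x0 + w, y0 + h)

        a, b = box(data), box(data)
        ca, fa = detect_contact(a, b)
        cb, fb = detect_contact(b, a)
        assert (ca, fa) == (cb, fb)
        assert 0.0 <= fa <= 1.0


class TestConfirmInteraction:
    def _crops(self, rng, same=True):
        prev = rng.integers(0, 255, size=(40, 40)).astype(np.uint8)
        cur = prev.copy() if same else rng.integers(0, 255, size=(40, 40)).astype(np.uint8)
        return prev, cur

    def test_static_identical_crops_not_confirmed(self, rng):
        prev, cur = self._crops(rng, same=True)
        assert not confirm_interaction(prev, cur, (0.0, 0.0), (False, False))

    def test_motion_confirms_regardless_of_ssim(self, rng):
        prev, cur = self._crops(rng, same=True)
        assert confirm_interaction(prev, cur, (5.0, 0.0), (False, False))

    def test_posture_change_confirms(self, rng):
        prev, cur = self._crops(rng, same=True)
        assert confirm_interaction(prev, cur, (0.0, 0.0), (True, False))

    def test_scene_change_confirms_via_ssim(self, rng):
        prev, cur = self._crops(rng, same=False)
        assert confirm_interaction(prev, cur, (0.0, 0.0), (False, False))

    def test_shape_mismatch_raises(self, rng):
        prev, _ = self._crops(rng)
        with pytest.raises(SchemaError):
            confirm_interaction(prev, prev[:20], (0.0, 0.0), (False, False))

    def test_no_crops_falls_back_to_motion_only(self):
        assert not confirm_interaction(None, None, (0.0, 0.0), (False, False))
        assert confirm_interaction(None, None, (3.0, 0.0), (False, False))


def _rect(x0, y0, w, h):
    return [(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)]


class TestFineInteraction:
    def test_mouth_on_tail(self):
        parts_a = {"body": _rect(0, 0, 50, 30), "mouth": _rect(48, 10, 8, 8)}
        parts_b = {"body": _rect(60, 0, 50, 30), "tail": _rect(48, 10, 8, 8)}
        label, actor = classify_fine_interaction(parts_a, parts_b)
        assert label == "mouth_to_tail" and actor == "a"

    def test_body_only_overlap(self):
        parts_a = {"body": _rect(0, 0, 50, 30)}
        parts_b = {"body": _rect(40, 0, 50, 30)}
        assert classify_fine_interaction(parts_a, parts_b)[0] == "body_contact"

    def test_head_to_head_symmetric_no_actor(self):
        sq = _rect(50, 10, 8, 8)
        parts_a = {"body": _rect(0, 0, 50, 30), "mouth": sq}
        parts_b = {"body": _rect(58, 0, 50, 30), "mouth": sq}
        label, actor = classify_fine_interaction(parts_a, parts_b)
        assert label == "head_to_head" and actor is None

    def test_nothing_above_min_iou_unclassified(self):
        parts_a = {"body": _rect(0, 0, 10, 10)}
        parts_b = {"body": _rect(100, 100, 10, 10)}
        assert classify_fine_interaction(parts_a, parts_b)[0] == "unclassified"

    def test_missing_both_bodies_raises(self):
        with pytest.raises(SchemaError):
            classify_fine_interaction({"mouth": _rect(0, 0, 5, 5)}, {"tail": _rect(0, 0, 5, 5)})

    def test_label_symmetric_in_participants(self, rng):
        for _ in range(20):
            parts_a, parts_b = _random_parts(rng), _random_parts(rng)
            la, _ = classify_fine_interaction(parts_a, parts_b)
            lb, _ = classify_fine_interaction(parts_b, parts_a)
            assert la == lb

    def test_matches_brute_force_max_iou_on_random_scenes(self, rng):
        from welfaremetrics.pig import _label_for_pair, _part_kind

        for _ in range(200):
            parts_a, parts_b = _random_parts(rng), _random_parts(rng)
            label, _ = classify_fine_interaction(parts_a, parts_b)
            ious = {
                (na, nb): part_iou(parts_a[na], parts_b[nb])
                for na, nb in itertools.product(parts_a, parts_b)
            }
            best_pair, best = max(sorted(ious.items()), key=lambda kv: kv[1])
            if best < 0.02:
                assert label == "unclassified"
            else:
                assert label == _label_for_pair(
                    _part_kind(best_pair[0]), _part_kind(best_pair[1])
                )


def _random_parts(rng):
    parts = {"body": _rect(rng.uniform(0, 60), rng.uniform(0, 60), 50, 30)}
    for name in ("mouth", "left_ear", "right_ear", "tail"):
        if rng.random() < 0.6:
            parts[name] = _rect(rng.uniform(0, 90), rng.uniform(0, 90), 8, 8)
    return parts


class TestEnrichment:
    HAY = _rect(0, 0, 30, 30)

    def test_overlap_with_hay(self):
        assert detect_enrichment_interaction(_rect(20, 20, 40, 40), "hay", self.HAY)

    def test_static_pole_no_overlap(self):
        assert not detect_enrichment_interaction(_rect(100, 100, 40, 40), "pole", self.HAY)

    def test_ball_movement_counts_without_overlap(self):
        assert detect_enrichment_interaction(
            _rect(100, 100, 40, 40), "ball", self.HAY, ball_step_cm=10.0
        )
        assert not detect_enrichment_interaction(
            _rect(100, 100, 40, 40), "ball", self.HAY, ball_step_cm=1.0
        )

    def test_unknown_name_raises(self):
        with pytest.raises(SchemaError):
            detect_enrichment_interaction(self.HAY, "trampoline", self.HAY)


class TestActivityReport:
    def test_900_frame_event_is_one_minute(self):
        ev = InteractionEvent(frame_span=(0, 899), participants=(1, 2), kind="animal_animal")
        rep = build_activity_report(
            [ev], {1: (60.0, 0.0), 2: (60.0, 0.0)}, {1: 0.0, 2: 0.0}, fps=15
        )
        assert rep.hourly_interaction_min.loc[1, 0] == pytest.approx(1.0)

    def test_no_events_zero_matrix(self):
        rep = build_activity_report([], {1: (1.0, 0.0)}, {}, fps=15)
        assert (rep.hourly_interaction_min.to_numpy() == 0).all()

    def test_minutes_conserved_across_bins(self, rng):
        fps = 15
        events = []
        for _ in range(30):
            lo = int(rng.integers(0, 3 * 3600 * fps))
            hi = lo + int(rng.integers(0, 2000))
            events.append(
                InteractionEvent(frame_span=(lo, hi), participants=(1, 2), kind="animal_animal")
            )
        rep = build_activity_report(
            events, {1: (0.0, 1.0), 2: (0.0, 1.0)}, {}, fps=fps
        )
        total_truth = sum(e.n_frames for e in events) / fps / 60.0
        for pig_id in (1, 2):
            assert rep.hourly_interaction_min.loc[pig_id].sum() == pytest.approx(total_truth)
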