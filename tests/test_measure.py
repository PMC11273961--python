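"""Post-processing: detection filter, bone measurement, flagging rules."""

import numpy as np
import pytest

from murimetry.io import BONES, SIDES, KeypointSet, keypoint_index
from murimetry.measure import (ABNORMAL_GEOMETRY, LENGTH_OUTLIER,
                               BoneMeasurement, filter_detections,
                               measure_bones, refine_measurements)
from murimetry.model import MouseDetection


def det_with_probs(probs):
    return [MouseDetection(np.array([0, 0, 10, 10]), p,
                           KeypointSet(np.zeros((12, 2))))
            for p in probs]


class TestFilterDetections:
    def test_strictly_greater_than_threshold(self):
        kept = filter_detections(det_with_probs([0.9, 0.4]))
        assert len(kept) == 1
        assert kept[0].top_view_prob == 0.9

    def test_probability_exactly_half_is_dropped(self):
        assert filter_detections(det_with_probs([0.5])) == []

    def test_empty_input(self):
        assert filter_detections([]) == []

    def test_idempotent_and_order_preserving(self):
        dets = det_with_probs([0.7, 0.9, 0.6])
        once = filter_detections(dets)
        assert [d.top_view_prob for d in once] == [0.7, 0.9, 0.6]
        assert filter_detections(once) == once


def make_keypoints(offset=(0.0, 0.0), scale=1.0):
    """A plausible 12-keypoint skeleton, scaled/translated."""
    coords = np.zeros((12, 2))
    base = {"pelvis": ((10, 10), (18, 25)), "femur": ((18, 26), (32, 40)),
            "tibia": ((32, 41), (38, 66))}
    for bone, (s, e) in base.items():
        for side, sign in (("L", -1), ("R", 1)):
            sx = 50 + sign * s[0]
            ex = 50 + sign * e[0]
            coords[keypoint_index(bone, side, "start")] = (sx, s[1])
            coords[keypoint_index(bone, side, "end")] = (ex, e[1])
    return KeypointSet(coords * scale + np.asarray(offset))


class TestMeasureBones:
    def test_three_four_five(self):
        coords = make_keypoints().coords.copy()
        coords[keypoint_index("tibia", "L", "start")] = (0.0, 0.0)
        coords[keypoint_index("tibia", "L", "end")] = (3.0, 4.0)
        det = MouseDetection(np.array([0, 0, 100, 100]), 0.9,
                             KeypointSet(coords))
        by_key = {(m.bone, m.side): m for m in measure_bones(det)}
        assert by_key[("tibia", "L")].length == pytest.approx(5.0)
        assert len(by_key) == 6

    def test_coincident_endpoints_flagged(self):
        coords = make_keypoints().coords.copy()
        coords[keypoint_index("femur", "R", "end")] = \
            coords[keypoint_index("femur", "R", "start")]
        det = MouseDetection(np.array([0, 0, 100, 100]), 0.9,
                             KeypointSet(coords))
        m = {(m.bone, m.side): m for m in measure_bones(det)}[("femur", "R")]
        assert m.length == 0.0
        assert ABNORMAL_GEOMETRY in m.flags

    def test_invisible_endpoint_gives_absent_length_not_exception(self):
        ks = make_keypoints()
        ks.visibility[keypoint_index("tibia", "R", "end")] = 0
        det = MouseDetection(np.array([0, 0, 100, 100]), 0.9, ks)
        m = {(m.bone, m.side): m for m in measure_bones(det)}[("tibia", "R")]
        assert m.length is None
        assert ABNORMAL_GEOMETRY in m.flags

    def test_translation_invariance_and_linear_scaling(self):
        d0 = MouseDetection(np.array([0, 0, 200, 200]), 0.9, make_keypoints())
        d1 = MouseDetection(np.array([0, 0, 200, 200]), 0.9,
                            make_keypoints(offset=(13.5, 7.25)))
        d2 = MouseDetection(np.array([0, 0, 200, 200]), 0.9,
                            make_keypoints(scale=2.0))
        l0 = {(m.bone, m.side): m.length for m in measure_bones(d0)}
        l1 = {(m.bone, m.side): m.length for m in measure_bones(d1)}
        l2 = {(m.bone, m.side): m.length for m in measure_bones(d2)}
        for key in l0:
            assert l1[key] == pytest.approx(l0[key], abs=1e-12)
            assert l2[key] == pytest.approx(2 * l0[key], rel=1e-12)

    def test_low_confidence_flag(self):
        ks = make_keypoints()
        ks.scores = np.full(12, 0.9)
        ks.scores[keypoint_index("pelvis", "L", "start")] = 0.1
        det = MouseDetection(np.array([0, 0, 100, 100]), 0.9, ks)
        meas = {(m.bone, m.side): m
                for m in measure_bones(det, score_threshold=0.5)}
        assert "low_confidence" in meas[("pelvis", "L")].flags
        assert "low_confidence" not in meas[("tibia", "R")].flags


def cohort_measurements(n_mice=10):
    out = []
    for i in range(n_mice):
        det = MouseDetection(np.array([0, 0, 200, 200]), 0.9,
                             make_keypoints())
        out.extend(measure_bones(det, image_id=f"img{i}.png", mouse_index=0))
    return out


class TestRefineMeasurements:
    def test_identical_cohort_has_no_flags(self):
        refined = refine_measurements(cohort_measurements())
        assert all(not m.flags for m in refined)

    def test_gross_outlier_flagged(self):
        meas = cohort_measurements()
        victim = next(m for m in meas
                      if m.bone == "femur" and m.image_id == "img3.png"
                      and m.side == "L")
        victim.length = victim.length * 10
        victim.end = victim.start + (victim.end - victim.start) * 10
        refined = refine_measurements(meas)
        flagged = [m for m in refined if m.length and m.length > 100]
        assert flagged and all(LENGTH_OUTLIER in m.flags for m in flagged)

    def test_swapped_keypoint_triggers_adjacency_flag(self):
        meas = cohort_measurements()
        tib = next(m for m in meas if m.bone == "tibia"
                   and m.side == "L" and m.image_id == "img2.png")
        # teleport the tibia start away from its femur end
        tib.start = tib.start + np.array([60.0, -40.0])
        tib.length = float(np.linalg.norm(tib.end - tib.start))
        refined = refine_measurements(meas)
        bad = {(m.bone, m.side) for m in refined
               if m.image_id == "img2.png" and ABNORMAL_GEOMETRY in m.flags}
        assert ("tibia", "L") in bad
        assert ("femur", "L") in bad

    def test_left_right_asymmetry_flagged(self):
        meas = cohort_measurements()
        left = next(m for m in meas if m.bone == "tibia"
                    and m.side == "L" and m.image_id == "img5.png")
        left.end = left.start + (left.end - left.start) * 1.6
        left.length = float(np.linalg.norm(left.end - left.start))
        refined = refine_measurements(meas, k=50.0)  # isolate asymmetry rule
        bad = {(m.bone, m.side) for m in refined
               if m.image_id == "img5.png" and ABNORMAL_GEOMETRY in m.flags}
        assert {("tibia", "L"), ("tibia", "R")} <= bad

    def test_never_alters_lengths_or_deletes(self):
        meas = cohort_measurements()
        meas[3].length = meas[3].length * 10
        meas[3].end = meas[3].start + (meas[3].end - meas[3].start) * 10
        refined = refine_measurements(meas)
        assert len(refined) == len(meas)
        for a, b in zip(meas, refined):
            assert a.length == b.length

    def test_too_few_lengths_skips_outlier_rule_with_warning(self):
        meas = cohort_measurements(1)  # one mouse: 2 lengths per bone class
        with pytest.warns(UserWarning, match="fewer than 3"):
            refined = refine_measurements(meas)
        assert all(LENGTH_OUTLIER not in m.flags for m in refined)


class TestBoneMeasurementInvariants:
    def test_length_must_match_endpoints(self):
        from murimetry.errors import ConfigError

        with pytest.raises(ConfigError):
            BoneMeasurement("i", 0, "tibia", "L", np.array([0.0, 0.0]),
                            np.array([3.0, 4.0]), 6.0)
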