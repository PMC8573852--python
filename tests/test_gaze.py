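"""Gaze QC: exclusion criteria, AOI assignment, visual-angle geometry."""

import itertools
import math

import pytest

from sightscore.gaze import (
    FixationEvent,
    QCThresholds,
    SaccadeEvent,
    TrialGaze,
    apply_datapoint_exclusions,
    apply_trial_exclusions,
    assign_fixations_to_aois,
    cm_to_visual_angle,
    visual_angle_to_cm,
)
from sightscore.score_model import ScreenGeometry, aoi_rectangles

GEOM = ScreenGeometry()
VALID = GEOM.valid_area_cm
CENTER_X, CENTER_Y = GEOM.image_cm[0] / 2, GEOM.staff_center_y_cm


def fix(n=10, duration=500.0, x=None, y=None):
    return [
        FixationEvent("t", i * 600.0, duration, x if x is not None else CENTER_X, y or CENTER_Y)
        for i in range(n)
    ]


def sacc(n=5, amplitude=3.0, direction="progressive"):
    return [SaccadeEvent("t", i * 600.0, amplitude, direction) for i in range(n)]


def trial(fixations=None, saccades=None):
    return TrialGaze("t", "m", fixations if fixations is not None else fix(),
                     saccades if saccades is not None else sacc())


class TestTrialExclusions:
    def test_clean_trial_retained(self):
        t = apply_trial_exclusions(trial(), VALID)
        assert not t.excluded and t.exclusion_reasons == []

    def test_too_few_fixations(self):
        t = apply_trial_exclusions(trial(fixations=fix(3)), VALID)
        assert t.excluded and "n_fixations<4" in t.exclusion_reasons

    def test_too_many_fixations(self):
        t = apply_trial_exclusions(trial(fixations=fix(41, duration=200.0)), VALID)
        assert "n_fixations>40" in t.exclusion_reasons

    def test_total_gaze_below_4571ms(self):
        t = apply_trial_exclusions(trial(fixations=fix(5, duration=100.0)), VALID)
        assert "total_gaze<4571" in t.exclusion_reasons

    def test_total_gaze_above_13714ms(self):
        t = apply_trial_exclusions(trial(fixations=fix(10, duration=1400.0)), VALID)
        assert t.excluded and "total_gaze>13714" in t.exclusion_reasons

    def test_boundary_total_gaze_retained(self):
        # exactly the overall reading time is not beyond it
        t = apply_trial_exclusions(trial(fixations=fix(10, duration=1371.4)), VALID)
        assert not t.excluded

    def test_fixations_outside_valid_area(self):
        outside = fix(6, x=0.5)  # far left of the valid area
        t = apply_trial_exclusions(trial(fixations=fix(6) + outside), VALID)
        assert "outside_valid_area>5" in t.exclusion_reasons

    def test_negative_outside_count_marks_corrupt_record(self):
        t = trial()
        t.n_outside_valid_area = -1
        t = apply_trial_exclusions(t, VALID)
        assert t.excluded and "outside_valid_area_negative_corrupt" in t.exclusion_reasons

    def test_multiple_violations_all_reported(self):
        t = apply_trial_exclusions(trial(fixations=fix(2, duration=100.0, x=0.5)), VALID)
        # 2 fixations outside the valid area does not trip the >5 criterion
        assert set(t.exclusion_reasons) == {"n_fixations<4", "total_gaze<4571"}


class TestDatapointExclusions:
    def test_few_saccades_blanks_saccade_measures_only(self):
        t = apply_datapoint_exclusions(trial(saccades=sacc(2, amplitude=10.0)))
        assert t.missing_measures == {"saccades"}
        assert not t.excluded  # trial itself retained

    def test_short_forward_distance(self):
        t = apply_datapoint_exclusions(trial(saccades=sacc(5, amplitude=2.0)))
        assert "saccades" in t.missing_measures  # 5 x 2 cm = 10 < 13

    def test_fix_saccade_count_mismatch(self):
        t = apply_datapoint_exclusions(
            trial(fixations=fix(15), saccades=sacc(5, amplitude=3.0))
        )
        assert "saccades" in t.missing_measures  # |15 - 5| > 8

    def test_clean_trial_unchanged(self):
        t = apply_datapoint_exclusions(trial())
        assert t.missing_measures == set()

    def test_regressive_distance_not_counted_as_forward(self):
        t = apply_datapoint_exclusions(
            trial(saccades=sacc(3, amplitude=10.0, direction="regressive"))
        )
        assert "saccades" in t.missing_measures


class TestOrderIndependence:
    def test_exclusion_flags_do_not_depend_on_application_order(self):
        cases = [
            trial(fixations=fix(3)),
            trial(fixations=fix(10, duration=1400.0)),
            trial(fixations=fix(2, duration=100.0), saccades=sacc(1)),
            trial(),
        ]
        for t in cases:
            a = apply_datapoint_exclusions(
                apply_trial_exclusions(
                    TrialGaze(t.trial_id, t.melody_id, t.fixations, t.saccades), VALID))
            b = apply_trial_exclusions(
                apply_datapoint_exclusions(
                    TrialGaze(t.trial_id, t.melody_id, t.fixations, t.saccades)), VALID)
            assert (a.excluded, sorted(a.exclusion_reasons), a.missing_measures) == (
                b.excluded, sorted(b.exclusion_reasons), b.missing_measures)


class TestAOIAssignment:
    AOIS = aoi_rectangles(GEOM)

    def in_aoi(self, k, t, duration=400.0, dx=0.1):
        left, top, right, bottom = self.AOIS[k]
        return FixationEvent("t", t, duration, left + dx, (top + bottom) / 2)

    def outside(self, t, duration=400.0):
        return FixationEvent("t", t, duration, 1.0, 1.0)

    def test_single_visit_is_all_first_pass(self):
        fixations = [self.in_aoi(0, i * 500.0) for i in range(3)]
        m = assign_fixations_to_aois(fixations, self.AOIS)[0]
        assert (m.n_fixations, m.n_first_pass, m.n_second_pass) == (3, 3, 0)
        assert m.gaze_duration_ms == m.first_pass_duration_ms == 1200.0
        assert not m.missing

    def test_revisit_counts_as_second_pass(self):
        fixations = [
            self.in_aoi(0, 0), self.in_aoi(0, 500), self.outside(1000), self.in_aoi(0, 1500)
        ]
        m = assign_fixations_to_aois(fixations, self.AOIS)[0]
        assert (m.n_first_pass, m.n_second_pass) == (2, 1)
        assert m.second_pass_duration_ms == 400.0

    def test_empty_aoi_is_missing(self):
        m = assign_fixations_to_aois([self.outside(0)], self.AOIS)[1]
        assert m.missing and m.n_fixations == 0

    def test_noisy_aoi_marked_missing(self):
        fixations = [self.in_aoi(2, i * 500.0) for i in range(7)]  # > 6 fixations
        m = assign_fixations_to_aois(fixations, self.AOIS)[2]
        assert m.n_fixations == 7 and m.missing

    def test_long_gaze_marked_missing(self):
        fixations = [self.in_aoi(1, i * 2500.0, duration=2100.0) for i in range(2)]
        m = assign_fixations_to_aois(fixations, self.AOIS)[1]
        assert m.gaze_duration_ms > 4000 and m.missing

    def test_pass_decomposition_conserves_counts_and_durations(self, rng):
        fixations = []
        t = 0.0
        for _ in range(40):
            k = int(rng.integers(-1, 3))
            dur = float(rng.uniform(100, 600))
            fixations.append(self.outside(t, dur) if k < 0 else self.in_aoi(k, t, dur))
            t += dur + 30
        for m in assign_fixations_to_aois(fixations, self.AOIS):
            later = m.n_fixations - m.n_first_pass - m.n_second_pass
            assert later >= 0
            assert m.first_pass_duration_ms + m.second_pass_duration_ms <= m.gaze_duration_ms + 1e-9

    def test_boundary_membership_left_top_inclusive(self):
        left, top, right, bottom = self.AOIS[0]
        on_left = FixationEvent("t", 0, 100, left, (top + bottom) / 2)
        on_right = FixationEvent("t", 0, 100, right, (top + bottom) / 2)
        assert assign_fixations_to_aois([on_left], self.AOIS)[0].n_fixations == 1
        assert assign_fixations_to_aois([on_right], self.AOIS)[0].n_fixations == 0

    def test_overlapping_aois_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assign_fixations_to_aois([], [(0, 0, 2, 2), (1, 1, 3, 3)])


class TestVisualAngle:
    def test_two_degrees_at_60cm_is_2_1cm(self):
        assert round(visual_angle_to_cm(2.0, 60.0), 1) == 2.1

    def test_one_and_a_half_degrees_is_1_57cm(self):
        assert round(visual_angle_to_cm(1.5, 60.0), 2) == 1.57

    def test_zero_angle(self):
        assert visual_angle_to_cm(0.0, 60.0) == 0.0

    def test_roundtrip_identity(self, rng):
        for _ in range(100):
            angle = float(rng.uniform(0, 90))
            d = float(rng.uniform(20, 120))
            assert math.isclose(
                cm_to_visual_angle(visual_angle_to_cm(angle, d), d), angle, abs_tol=1e-9
            )

    def test_strictly_increasing_in_both_arguments(self):
        angles = [0.5, 1, 2, 5, 10, 45]
        vals = [visual_angle_to_cm(a, 60) for a in angles]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        dists = [30, 60, 90, 120]
        vals = [visual_angle_to_cm(2, d) for d in dists]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            visual_angle_to_cm(180.0, 60.0)
        with pytest.raises(ValueError):
            visual_angle_to_cm(2.0, 0.0)
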