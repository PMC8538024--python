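"""Clinical metrology: calibration, measurement rules, quantization, grading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lidmetrics.eyegen import NoiseConfig, make_eye_scenes, render_eye
from lidmetrics.landmarks import LandmarkAnnotation
from lidmetrics.metrology import (MeasurementRecord, consensus, grade_ptosis,
                                  measure_lf, measure_mrd1, measure_mrd2,
                                  mm_per_pixel, quantize_mm)


def ann(reflex=(200.0, 150.0), upper=(200.0, 112.0), lower=(200.0, 205.0)):
    return LandmarkAnnotation("img", reflex, upper, lower, source="ground_truth")


class TestCalibration:
    def test_square_side_200px(self):
        corners = [(0, 0), (200, 0), (200, 200), (0, 200)]
        assert mm_per_pixel(corners) == pytest.approx(0.1)

    def test_mean_of_uneven_sides(self):
        corners = [(0, 0), (198, 0), (202, 200), (0, 202)]
        lengths = [np.hypot(*(np.subtract(corners[(i + 1) % 4], corners[i])))
                   for i in range(4)]
        assert mm_per_pixel(corners) == pytest.approx(20.0 / np.mean(lengths))

    def test_collinear_corners_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            mm_per_pixel([(0, 0), (1, 0), (2, 0), (3, 0)])


class TestMeasurements:
    def test_mrd1_quantized_to_quarter_mm(self):
        # 38 px at 0.1 mm/px -> 3.8 mm -> nearest 0.25 step is 3.75
        assert measure_mrd1(ann(), 0.1) == pytest.approx(3.75)

    def test_mrd1_no_reflex_is_zero(self):
        assert measure_mrd1(ann(reflex=None), 0.1) == 0.0

    def test_mrd1_margin_at_reflex_height(self):
        assert measure_mrd1(ann(upper=(200.0, 150.0)), 0.1) == 0.0

    def test_mrd2_by_rule(self):
        assert measure_mrd2(ann(), 0.1) == pytest.approx(5.5)
        assert measure_mrd2(ann(), 0.05) == pytest.approx(2.75)
        assert measure_mrd2(ann(lower=(200.0, 150.0)), 0.1) == 0.0

    def test_lf_by_rule(self):
        up = ann(upper=(200.0, 100.0))
        down = ann(upper=(200.0, 220.0))
        assert measure_lf(up, down, 0.1) == pytest.approx(12.0)

    def test_lf_identical_margins_warns(self):
        a = ann()
        with pytest.warns(UserWarning, match="physiologic"):
            assert measure_lf(a, a, 0.1) == 0.0

    def test_lf_missing_annotation_is_exclusion(self):
        from lidmetrics.normalize import MergeExclusion
        with pytest.raises(MergeExclusion):
            measure_lf(ann(), None, 0.1)

    def test_scale_linearity_prequantization(self):
        a = ann()
        for f in (0.5, 2.0, 3.0):
            assert measure_mrd1(a, 0.1 * f, quantize=False) == pytest.approx(
                f * measure_mrd1(a, 0.1, quantize=False))
            assert measure_mrd2(a, 0.1 * f, quantize=False) == pytest.approx(
                f * measure_mrd2(a, 0.1, quantize=False))

    def test_roundtrip_against_generator(self):
        """Measured lf on a rendered lf=12.1 eye is 12.0 or 12.25 (quantization)."""
        scenes = make_eye_scenes("S", "left", 2.5, 5.5, 12.1, mm_per_px=0.2)
        _, up = render_eye(scenes["up"], NoiseConfig.none(), seed=0)
        _, down = render_eye(scenes["down"], NoiseConfig.none(), seed=0)
        assert measure_lf(up, down, 0.2) in (12.0, 12.25)
        assert measure_lf(up, down, 0.2, quantize=False) == pytest.approx(12.1, abs=0.2)


class TestQuantization:
    @given(st.floats(-20, 20))
    @settings(max_examples=100, derandomize=True)
    def test_quantize_grid_and_distance(self, v):
        q = quantize_mm(v)
        assert abs(q / 0.25 - round(q / 0.25)) < 1e-9
        assert abs(q - v) <= 0.125 + 1e-9

    def test_half_away_from_zero(self):
        assert quantize_mm(0.125) == 0.25
        assert quantize_mm(-0.125) == -0.25
        assert quantize_mm(3.8) == 3.75


class TestConsensus:
    def test_mean_not_requantized(self):
        a = MeasurementRecord("e1", mrd1_mm=3.75, source="rater", rater_id="A")
        b = MeasurementRecord("e1", mrd1_mm=4.00, source="rater", rater_id="B")
        assert consensus(a, b).mrd1_mm == pytest.approx(3.875)

    def test_identical_inputs(self):
        a = MeasurementRecord("e1", mrd1_mm=3.0, mrd2_mm=5.0, source="rater")
        out = consensus(a, a)
        assert out.mrd1_mm == 3.0 and out.mrd2_mm == 5.0

    def test_one_missing_errors(self):
        a = MeasurementRecord("e1", mrd1_mm=3.0, source="rater")
        b = MeasurementRecord("e1", source="rater")
        with pytest.raises(ValueError, match="both raters"):
            consensus(a, b)

    def test_different_eyes_error(self):
        a = MeasurementRecord("e1", mrd1_mm=3.0, source="rater")
        b = MeasurementRecord("e2", mrd1_mm=3.0, source="rater")
        with pytest.raises(ValueError, match="same eye"):
            consensus(a, b)


class TestGrading:
    @pytest.mark.parametrize("mrd1,grade", [
        (0.0, "severe"), (1.99, "severe"), (2.0, "moderate"), (2.9, "moderate"),
        (3.0, "mild"), (3.5, "mild"), (4.0, "none"), (5.5, "none"),
    ])
    def test_half_open_bins(self, mrd1, grade):
        assert grade_ptosis(mrd1) == grade

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            grade_ptosis(-0.5)

    @given(st.floats(0, 8), st.floats(0, 8))
    @settings(max_examples=100, derandomize=True)
    def test_grade_monotonic_in_mrd1(self, a, b):
        order = {"severe": 3, "moderate": 2, "mild": 1, "none": 0}
        lo, hi = sorted([a, b])
        assert order[grade_ptosis(hi)] <= order[grade_ptosis(lo)]


class TestRecordInvariants:
    def test_negative_rater_mrd1_rejected(self):
        with pytest.raises(ValueError, match="clamped"):
            MeasurementRecord("e1", mrd1_mm=-1.0, source="rater")

    def test_model_predictions_may_be_negative(self):
        rec = MeasurementRecord("e1", mrd1_mm=-0.4, source="model")
        assert rec.mrd1_mm == -0.4

    def test_quantized_flag_enforced(self):
        with pytest.raises(ValueError, match="multiple"):
            MeasurementRecord("e1", mrd1_mm=3.8, source="rater", quantized=True)
        MeasurementRecord("e1", mrd1_mm=3.75, source="rater", quantized=True)
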