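"""Tests of the synthetic leg generator and the anatomical measurements."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteosim import (
    MODEL_1,
    MODEL_2,
    ConstructionError,
    InvalidPlaneError,
    LegParameters,
    Plane,
    generate_synthetic_leg,
    landmarks_from_json,
    landmarks_to_json,
    measure_antecurvatum,
    measure_femoral_torsion,
    measure_mldfa,
    measure_projected_hka,
    mirror_landmarks,
    shaft_point_at_level,
    split_fragments,
)
from osteosim.leg import _polyline_arclengths


def leg_params(**overrides):
    base = dict(
        femoral_torsion_deg=15.0,
        antecurvatum_deg=10.0,
        mldfa_deg=87.0,
        preop_hka_valgus_deg=0.0,
    )
    base.update(overrides)
    return LegParameters(**base)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "params,torsion,ante,mldfa,hka",
        [
            (MODEL_1, 42.0, 8.0, 85.0, 2.4),
            (MODEL_2, -6.0, 14.0, 86.0, 5.1),
        ],
        ids=["antetorsion-model", "retrotorsion-model"],
    )
    def test_study_models_round_trip(self, params, torsion, ante, mldfa, hka):
        lm = generate_synthetic_leg(params)
        assert measure_femoral_torsion(lm) == pytest.approx(torsion, abs=0.1)
        assert measure_antecurvatum(lm) == pytest.approx(ante, abs=0.2)
        assert measure_mldfa(lm) == pytest.approx(mldfa, abs=0.1)
        assert measure_projected_hka(lm).hka_valgus_deg == pytest.approx(
            hka, abs=0.05
        )

    @given(
        torsion=st.floats(-25.0, 55.0),
        ante=st.floats(0.0, 25.0),
        mldfa=st.floats(78.0, 94.0),
        hka=st.floats(-10.0, 10.0),
    )
    def test_any_valid_parameters_round_trip(self, torsion, ante, mldfa, hka):
        params = leg_params(
            femoral_torsion_deg=torsion,
            antecurvatum_deg=ante,
            mldfa_deg=mldfa,
            preop_hka_valgus_deg=hka,
        )
        lm = generate_synthetic_leg(params)
        assert measure_femoral_torsion(lm) == pytest.approx(torsion, abs=0.2)
        assert measure_antecurvatum(lm) == pytest.approx(ante, abs=0.2)
        assert measure_mldfa(lm) == pytest.approx(mldfa, abs=0.2)
        assert measure_projected_hka(lm).hka_valgus_deg == pytest.approx(
            hka, abs=0.2
        )

    def test_generation_is_deterministic(self):
        a = generate_synthetic_leg(MODEL_1)
        b = generate_synthetic_leg(MODEL_1)
        np.testing.assert_array_equal(a.shaft_polyline, b.shaft_polyline)
        for name in ("hip_center", "lesser_trochanter", "ankle_center"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_straight_leg_is_collinear(self):
        lm = generate_synthetic_leg(
            leg_params(
                femoral_torsion_deg=0.0,
                antecurvatum_deg=0.0,
                mldfa_deg=90.0,
                preop_hka_valgus_deg=0.0,
            )
        )
        hip, knee, ankle = lm.hip_center, lm.knee_center, lm.ankle_center
        cross = np.cross(hip - knee, ankle - knee)
        assert np.linalg.norm(cross) < 1e-9 * np.linalg.norm(hip - ankle)
        # neck lies in the frontal plane (no anterior component)
        assert abs(lm.neck_axis[0]) < 1e-12
        assert measure_projected_hka(lm).hka_valgus_deg == pytest.approx(0.0)

    def test_mirroring_flips_torsion_and_hka(self, model1_leg):
        mirrored = mirror_landmarks(model1_leg)
        assert measure_femoral_torsion(mirrored) == pytest.approx(-42.0, abs=1e-9)
        # in a fixed external AP view the valgus sign flips with the side
        assert measure_projected_hka(
            mirrored, "global_fixed"
        ).hka_valgus_deg == pytest.approx(-2.4, abs=1e-9)
        # the limb-intrinsic (patella-forward) view is chirality-aware and
        # preserves the magnitude
        assert abs(
            measure_projected_hka(mirrored, "knee_anchored").hka_valgus_deg
        ) == pytest.approx(2.4, abs=1e-9)
        assert measure_mldfa(mirrored) == pytest.approx(85.0, abs=1e-9)


class TestMeasurements:
    def test_mldfa_on_hand_built_construction(self):
        """Four points placed by explicit trigonometry: mechanical axis
        vertical, joint line tilted so the lateral angle is 87 deg."""
        from osteosim.leg import LegLandmarks

        t = np.radians(87.0)
        jl = np.array([0.0, np.cos(np.pi - t), np.sin(np.pi - t)])  # medial dir
        lm = LegLandmarks(
            hip_center=[0, 400, 0],
            knee_center=[0, 0, 0],
            ankle_center=[0, -380, 0],
            lesser_trochanter=[0, 330, 0],
            posterior_condyle_medial=[-25, 0, 40],
            posterior_condyle_lateral=[-25, 0, -40],
            distal_condyle_medial=40 * jl,
            distal_condyle_lateral=-40 * jl,
            neck_axis=[0, np.sin(np.radians(37)), np.cos(np.radians(37))],
            shaft_polyline=np.array([[0.0, 350.0, 0.0], [0, 200, 0], [0, 0, 0]]),
        )
        assert measure_mldfa(lm) == pytest.approx(87.0, abs=1e-9)

    def test_perpendicular_joint_line_is_90(self):
        lm = generate_synthetic_leg(leg_params(mldfa_deg=90.0))
        assert measure_mldfa(lm) == pytest.approx(90.0, abs=1e-9)

    def test_straight_polyline_has_zero_antecurvatum(self):
        lm = generate_synthetic_leg(leg_params(antecurvatum_deg=0.0))
        assert measure_antecurvatum(lm) == pytest.approx(0.0, abs=1e-9)

    def test_zero_torsion_neck_parallel_to_condylar_tangent(self):
        lm = generate_synthetic_leg(leg_params(femoral_torsion_deg=0.0))
        assert measure_femoral_torsion(lm) == pytest.approx(0.0, abs=1e-9)


class TestShaftPointAtLevel:
    def test_zero_offset_is_lt_level(self, model1_leg):
        p = shaft_point_at_level(model1_leg, "subtrochanteric", 0.0)
        # the LT landmark lies on the shaft polyline by construction
        assert np.linalg.norm(p - model1_leg.lesser_trochanter) < 1e-6

    def test_subtrochanteric_offset_matches_arclength_oracle(self, model1_leg):
        p = shaft_point_at_level(model1_leg, "subtrochanteric", 45.0)
        poly = model1_leg.shaft_polyline
        cum = _polyline_arclengths(poly)
        # oracle: cumulative-chord interpolation done independently
        d_lt = np.linalg.norm(poly - model1_leg.lesser_trochanter, axis=1)
        s_target = cum[int(np.argmin(d_lt))] + 45.0
        idx = np.searchsorted(cum, s_target)
        w = (s_target - cum[idx - 1]) / (cum[idx] - cum[idx - 1])
        oracle = poly[idx - 1] + w * (poly[idx] - poly[idx - 1])
        # the oracle quantises the LT level to the nearest polyline vertex
        # (spacing ~1.5 mm), so agreement is expected to within one vertex
        assert np.linalg.norm(p - oracle) < 1.0

    def test_supracondylar_offset_from_distal_end(self, model1_leg):
        p = shaft_point_at_level(model1_leg, "supracondylar", 60.0)
        poly = model1_leg.shaft_polyline
        cum = _polyline_arclengths(poly)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        # independent check: walk back 60 mm of chords from the distal end
        s = cum[-1] - 60.0
        i = int(np.searchsorted(cum, s))
        w = (s - cum[i - 1]) / seg[i - 1]
        oracle = poly[i - 1] + w * (poly[i] - poly[i - 1])
        np.testing.assert_allclose(p, oracle, atol=1e-9)

    def test_offset_outside_span_raises(self, model1_leg):
        with pytest.raises(ConstructionError):
            shaft_point_at_level(model1_leg, "supracondylar", 1e6)

    def test_unknown_site_raises(self, model1_leg):
        with pytest.raises(ValueError):
            shaft_point_at_level(model1_leg, "midshaft", 10.0)


class TestSplitFragments:
    def test_subtrochanteric_split(self, model1_leg):
        p = shaft_point_at_level(model1_leg, "subtrochanteric", 45.0)
        plane = Plane(point=p, normal=model1_leg.mechanical_axis_direction)
        fa = split_fragments(model1_leg, plane)
        assert {"hip_center", "lesser_trochanter"} <= fa.proximal
        assert {
            "knee_center",
            "ankle_center",
            "posterior_condyle_medial",
            "posterior_condyle_lateral",
            "distal_condyle_medial",
            "distal_condyle_lateral",
        } <= fa.distal
        assert fa.proximal.isdisjoint(fa.distal)

    def test_supracondylar_split_keeps_lt_proximal(self, model1_leg):
        p = shaft_point_at_level(model1_leg, "supracondylar", 60.0)
        plane = Plane(point=p, normal=model1_leg.mechanical_axis_direction)
        fa = split_fragments(model1_leg, plane)
        assert "lesser_trochanter" in fa.proximal
        assert "knee_center" in fa.distal

    def test_plane_above_hip_is_invalid(self, model1_leg):
        plane = Plane(
            point=model1_leg.hip_center + np.array([0.0, 50.0, 0.0]),
            normal=[0, 1, 0],
        )
        with pytest.raises(InvalidPlaneError):
            split_fragments(model1_leg, plane)

    def test_landmark_on_plane_is_invalid(self, model1_leg):
        plane = Plane(point=model1_leg.knee_center, normal=[0, 1, 0])
        with pytest.raises(InvalidPlaneError):
            split_fragments(model1_leg, plane)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"femoral_torsion_deg": 70.0},
            {"mldfa_deg": 60.0},
            {"antecurvatum_deg": -1.0},
            {"femur_length_mm": -5.0},
            {"preop_hka_valgus_deg": 40.0},
        ],
    )
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ConstructionError):
            leg_params(**kwargs)


class TestSerialisation:
    def test_json_round_trip(self, model2_leg):
        text = landmarks_to_json(model2_leg)
        back = landmarks_from_json(text)
        np.testing.assert_allclose(back.hip_center, model2_leg.hip_center)
        np.testing.assert_allclose(back.neck_axis, model2_leg.neck_axis)
        np.testing.assert_allclose(
            back.shaft_polyline, model2_leg.shaft_polyline
        )
        assert measure_femoral_torsion(back) == pytest.approx(
            measure_femoral_torsion(model2_leg), abs=1e-9
        )
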