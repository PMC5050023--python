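"""Plate-frame fitting, delta/swivel measurement and the 1D projection theory."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ktswivel import (
    KinetochorePair,
    delta1d_exact,
    delta1d_first_order,
    fit_plate_frame,
    measure_delta,
    measure_delta1d,
    measure_swivel,
    plate_thickness,
    project_delta_xy,
)
from ktswivel.geometry import delta_components, swivel_components

from conftest import planar_pair


# ---------------------------------------------------------------------------
# plate frame


class TestPlateFrame:
    def test_recovers_plane_normal_and_origin(self, rng):
        pts = np.column_stack([
            np.full(50, 5000.0),
            rng.uniform(-4000, 4000, 50),
            rng.uniform(-4000, 4000, 50),
        ])
        frame = fit_plate_frame(pts)
        assert abs(abs(frame.basis[0] @ [1, 0, 0]) - 1) < 1e-9
        assert frame.origin[0] == pytest.approx(5000.0)

    def test_basis_is_right_handed(self, rng):
        pts = rng.normal(0, 1, (40, 3)) * [100, 3000, 3000]
        frame = fit_plate_frame(pts)
        assert np.linalg.det(frame.basis) == pytest.approx(1.0, abs=1e-12)

    def test_rotated_plate_normal_recovered_under_noise(self, rng):
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        pts = rng.normal(0, 1, (200, 3)) * [100, 3500, 3500]
        pts = pts @ rot.T + rng.normal(0, 100, (200, 3))
        frame = fit_plate_frame(pts)
        true_normal = rot @ np.array([1.0, 0, 0])
        angle = np.degrees(np.arccos(abs(frame.basis[0] @ true_normal)))
        assert angle < 1.0

    def test_degenerate_cloud_rejected(self):
        line = np.outer(np.linspace(0, 1, 20), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_plate_frame(line)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_plate_frame(np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# delta


class TestMeasureDelta:
    def test_three_four_five_triangle(self):
        pair = KinetochorePair(0, [[0, 0, 0], [0, 1000, 0]],
                               [[30, 40, 0], [0, 1100, 0]])
        m0, _ = measure_delta(pair)
        assert m0.delta3d == pytest.approx(50.0)
        assert m0.delta2d == pytest.approx(50.0)
        assert m0.delta_z == 0.0
        assert m0.z_filter_pass

    def test_zero_delta_when_outer_equals_inner(self):
        pair = KinetochorePair(0, [[0, 0, 0], [0, 1000, 0]],
                               [[0, 0, 0], [0, 1000, 0]])
        m0, m1 = measure_delta(pair)
        for m in (m0, m1):
            assert m.delta3d == 0.0 and m.delta2d == 0.0 and m.delta1d == 0.0

    def test_z_component_filter_at_100nm(self):
        pair = KinetochorePair(0, [[0, 0, 0], [0, 1000, 0]],
                               [[0, 50, 150], [0, 1100, 0]])
        m0, m1 = measure_delta(pair)
        assert not m0.z_filter_pass
        assert m1.z_filter_pass

    def test_coincident_inner_markers_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            KinetochorePair(0, [[0, 0, 0], [0, 0, 0]],
                            [[50, 0, 0], [0, 50, 0]])

    def test_inter_sister_distances(self):
        pair = planar_pair(0.0, 0.0, dy=950.0)
        m0, _ = measure_delta(pair)
        assert m0.d3d == pytest.approx(950.0)
        assert m0.d2d == pytest.approx(950.0)
        # outer marker 100 nm beyond the far sister's inner marker
        assert m0.epsilon_y == pytest.approx(1050.0)


class TestMeasureDelta1D:
    def test_collinear_outward_gives_plus_delta(self):
        assert measure_delta1d(planar_pair(0.0, 0.0)) == pytest.approx(100.0)

    def test_both_perpendicular_gives_pythagoras_value(self):
        pair = planar_pair(90.0, 90.0)
        expected = (np.hypot(1000.0, 200.0) - 1000.0) / 2
        assert measure_delta1d(pair) == pytest.approx(expected)
        assert measure_delta1d(pair) == pytest.approx(9.90, abs=0.01)

    def test_fully_rotated_inward_gives_minus_delta(self):
        assert measure_delta1d(planar_pair(180.0, 180.0)) == pytest.approx(-100.0)

    def test_missing_outer_marker_gives_nan(self):
        pair = planar_pair(0.0, 0.0)
        pair.outer[1] = np.nan
        assert np.isnan(measure_delta1d(pair))


# ---------------------------------------------------------------------------
# swivel


class TestMeasureSwivel:
    @pytest.mark.parametrize("theta, epsilon_label", [
        (0.0, "outer points away from the sister"),
        (90.0, "outer perpendicular to sister axis"),
        (180.0, "outer points toward the sister"),
    ])
    def test_cosine_rule_reference_angles(self, theta, epsilon_label):
        m0, m1 = measure_swivel(planar_pair(theta, theta))
        assert abs(m0.y_swivel) == pytest.approx(theta, abs=1e-9)
        assert abs(m1.y_swivel) == pytest.approx(theta, abs=1e-9)

    def test_y_swivel_sign_follows_side_of_sister_axis(self):
        m0, _ = measure_swivel(planar_pair(35.0, 0.1))
        assert m0.y_swivel == pytest.approx(35.0)
        m0, _ = measure_swivel(planar_pair(-35.0, 0.1))
        assert m0.y_swivel == pytest.approx(-35.0)

    def test_swivel3d_matches_y_swivel_for_planar_pairs(self):
        m0, _ = measure_swivel(planar_pair(52.0, 10.0))
        assert m0.swivel3d == pytest.approx(52.0)

    def test_twist_zero_for_axis_along_plate_normal(self):
        pair = KinetochorePair(0, [[0, 0, 0], [950, 0, 0]],
                               [[-90, 10, 0], [1040, 10, 0]])
        m0, _ = measure_swivel(pair)
        assert m0.twist == pytest.approx(0.0, abs=1e-9)

    def test_twist_for_tilted_axis(self):
        c, s = np.cos(np.radians(25)), np.sin(np.radians(25))
        axis = np.array([c, s, 0.0])
        inner = np.array([[0, 0, 0], 950 * axis])
        outer = inner + 98 * np.array([-axis, axis])
        m0, _ = measure_swivel(KinetochorePair(0, inner, outer))
        assert m0.twist == pytest.approx(25.0, abs=1e-9)

    def test_kmt_angle_equals_y_swivel_for_collinear_axis(self):
        pair = planar_pair(40.0, -25.0)
        v = pair.outer - pair.inner
        kmt = v / np.linalg.norm(v, axis=1, keepdims=True)
        m0, m1 = measure_swivel(pair, kmt_axis=kmt)
        assert m0.kmt_angle == pytest.approx(m0.y_swivel, abs=1e-9)
        assert m1.kmt_angle == pytest.approx(m1.y_swivel, abs=1e-9)

    def test_zero_delta_y_is_rejected(self):
        pair = KinetochorePair(0, [[0, 0, 0], [0, 1000, 0]],
                               [[0, 0, 90], [0, 1100, 0]])
        with pytest.raises(ValueError, match="y-swivel undefined"):
            measure_swivel(pair)

    def test_cosine_rule_agrees_with_projected_dot_product(self, rng):
        """|y-swivel| from the triangle cosine rule equals the xy dot-product
        angle between the away direction and the intra-kinetochore vector."""
        for _ in range(200):
            t1, t2 = rng.uniform(-179.9, 179.9, 2)
            pair = planar_pair(t1, t2, dy=rng.uniform(600, 1400),
                               delta1=rng.uniform(20, 200),
                               delta2=rng.uniform(20, 200))
            m0, m1 = measure_swivel(pair)
            for m, i, j in ((m0, 0, 1), (m1, 1, 0)):
                v = (pair.outer[i] - pair.inner[i])[:2]
                a = (pair.inner[i] - pair.inner[j])[:2]
                dot = np.degrees(np.arccos(
                    v @ a / (np.linalg.norm(v) * np.linalg.norm(a))))
                assert abs(abs(m.y_swivel) - dot) < 1e-6


# ---------------------------------------------------------------------------
# 1D projection theory


class TestDelta1DTheory:
    def test_collinear_configuration(self):
        assert delta1d_exact(1000.0, 100.0, 100.0, 0.0, 0.0) == pytest.approx(100.0)
        assert delta1d_first_order(100.0, 100.0, 0.0, 0.0) == pytest.approx(100.0)

    def test_perpendicular_configuration(self):
        assert delta1d_exact(1000.0, 100.0, 100.0, 90.0, 90.0) == pytest.approx(
            9.902, abs=5e-4)
        assert delta1d_first_order(100.0, 100.0, 90.0, 90.0) == pytest.approx(0.0)

    def test_oblique_configuration_against_coordinates(self):
        assert delta1d_exact(1000.0, 100.0, 100.0, 120.0, 120.0) == pytest.approx(
            -41.74, abs=5e-3)
        assert delta1d_exact(1000.0, 100.0, 100.0, 120.0, 120.0) == \
            pytest.approx(measure_delta1d(planar_pair(120.0, 120.0)), abs=1e-9)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        dy=st.floats(500, 2000),
        d1=st.floats(0.1, 250),
        d2=st.floats(0.1, 250),
        t1=st.floats(-180, 180),
        t2=st.floats(-180, 180),
    )
    def test_closed_form_equals_coordinate_brute_force(self, dy, d1, d2, t1, t2):
        pair = planar_pair(t1, t2, dy=dy, delta1=d1, delta2=d2)
        assert delta1d_exact(dy, d1, d2, t1, t2) == pytest.approx(
            measure_delta1d(pair), abs=1e-9)

    def test_first_order_error_bounded_by_ten_percent_at_ratio_0p1(self):
        th = np.arange(-180.0, 181.0, 1.0)
        t1, t2 = np.meshgrid(th, th)
        err = np.abs(delta1d_exact(1000.0, 100.0, 100.0, t1, t2)
                     - delta1d_first_order(100.0, 100.0, t1, t2)) / 100.0
        assert err.max() <= 0.10
        assert err.max() > 0.09  # the bound is essentially attained

    def test_projection_helper(self):
        assert project_delta_xy(98.0, 0.0) == pytest.approx(98.0)
        assert project_delta_xy(98.0, 60.0) == pytest.approx(49.0)


class TestProjectionOrdering:
    def test_delta_orderings_on_random_configurations(self, rng):
        """delta3d >= delta2d >= delta3d*|cos theta_z|, and the pair's 1D
        delta never exceeds the mean of its sisters' 3D deltas."""
        n = 10_000
        inner0 = rng.normal(0, 500, (n, 3))
        inner1 = inner0 + rng.normal(0, 1, (n, 3)) * 300 + [0, 950, 0]
        outer0 = inner0 + rng.normal(0, 60, (n, 3))
        outer1 = inner1 + rng.normal(0, 60, (n, 3))
        c0 = delta_components(inner0, outer0, inner1, outer1)
        c1 = delta_components(inner1, outer1, inner0, outer0)
        for c in (c0, c1):
            tz = np.degrees(np.arcsin(
                np.abs(c["delta_z"]) / np.maximum(c["delta3d"], 1e-12)))
            assert np.all(c["delta3d"] >= c["delta2d"] - 1e-9)
            assert np.all(c["delta2d"] >= c["delta3d"] * np.abs(
                np.cos(np.radians(tz))) - 1e-9)
        assert np.all(c0["delta1d"] <= 0.5 * (c0["delta3d"] + c1["delta3d"]) + 1e-9)


# ---------------------------------------------------------------------------
# plate thickness


class TestPlateThickness:
    def test_zero_spread_is_late(self):
        t, stage = plate_thickness(np.full(20, 1234.5))
        assert t == 0.0 and stage == "late"

    def test_gaussian_spread_recovered(self, rng):
        x = rng.normal(0, 700.0, 200)
        t, stage = plate_thickness(x)
        assert t == pytest.approx(0.7, rel=0.10)
        assert stage == "early"

    def test_mid_stage_between_bins(self, rng):
        x = rng.normal(0, 500.0, 5000)
        t, stage = plate_thickness(x)
        assert stage == "mid"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            plate_thickness(np.zeros(5))
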