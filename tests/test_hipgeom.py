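"""Geometric engine: circle fit, neck axis, alpha angle, LCEA, mJSW."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from hipmorph.hipgeom import (ConfigurationError, CircleFit, DegenerateGeometryError,
                              LandmarkSet, LandmarkTemplate, NoDepartureError,
                              compute_alpha_angle, compute_lcea, compute_mjsw,
                              estimate_neck_axis, fit_circle, measure_hip,
                              polyline_min_distance, read_landmarks_csv,
                              write_landmarks_csv)
from hipmorph.synthetic_hip import ShapeParams, generate_hip_outline


def circle_points(centre, radius, angles_deg):
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return np.asarray(centre) + radius * np.column_stack([np.cos(a), np.sin(a)])


# ---------------------------------------------------------------------------
# circle of best fit
# ---------------------------------------------------------------------------


class TestFitCircle:
    def test_exact_circle_recovered(self):
        pts = circle_points((3.0, -2.0), 5.0, np.arange(0, 360, 45))
        fit = fit_circle(pts)
        assert np.allclose(fit.centre, [3.0, -2.0], atol=1e-9)
        assert fit.radius == pytest.approx(5.0, abs=1e-9)
        assert fit.rms_radial_residual == pytest.approx(0.0, abs=1e-9)

    def test_circumscribed_right_triangle(self):
        fit = fit_circle([(0, 0), (2, 0), (0, 2)])
        assert np.allclose(fit.centre, [1.0, 1.0], atol=1e-9)
        assert fit.radius == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_matches_brute_force_least_squares_oracle(self, rng):
        """Noisy 14-point arc agrees with derivative-free minimisation of
        the geometric objective to within 1e-3 mm."""
        angles = np.linspace(0, 330, 14)
        pts = circle_points((1.0, 2.0), 10.0, angles)
        pts += (rng.normal(0, 0.1, 14)[:, None]
                * (pts - [1.0, 2.0]) / np.linalg.norm(pts - [1.0, 2.0], axis=1)[:, None])

        def objective(x):
            return np.sum((np.linalg.norm(pts - x[:2], axis=1) - x[2]) ** 2)

        oracle = minimize(objective, x0=[0.8, 2.2, 9.5], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        fit = fit_circle(pts)
        assert np.allclose(fit.centre, oracle.x[:2], atol=1e-3)
        assert fit.radius == pytest.approx(oracle.x[2], abs=1e-3)

    @pytest.mark.parametrize("pts", [
        [(0, 0), (1, 1)],
        [(0, 0), (1, 1), (2, 2), (3, 3)],
    ])
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(DegenerateGeometryError):
            fit_circle(pts)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(angle=st.floats(0, 2 * np.pi), tx=st.floats(-50, 50), ty=st.floats(-50, 50),
           seed=st.integers(0, 1000))
    def test_rigid_motion_equivariance_and_permutation_invariance(self, angle, tx, ty, seed):
        r = np.random.default_rng(seed)
        pts = circle_points((0, 0), 8.0, r.uniform(0, 360, 10)) + r.normal(0, 0.3, (10, 2))
        sv = np.linalg.svd(pts - pts.mean(0), compute_uv=False)
        if sv[-1] / sv[0] < 1e-3:
            return
        base = fit_circle(pts)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = fit_circle(pts[::-1] @ rot.T + [tx, ty])
        # 1e-9 relative to the coordinate scale (|t| up to 50 mm)
        assert np.allclose(moved.centre, base.centre @ rot.T + [tx, ty], atol=1e-7)
        assert moved.radius == pytest.approx(base.radius, abs=1e-7)


# ---------------------------------------------------------------------------
# neck axis
# ---------------------------------------------------------------------------


class TestNeckAxis:
    def test_symmetric_neck_centre_on_midline(self, clean_hip, template):
        landmarks, _, params = clean_hip
        circle = fit_circle(landmarks.get(template.head_circle_range))
        axis = estimate_neck_axis(landmarks, template, circle)
        theta = np.radians(180.0 + params.neck_axis_angle_deg)
        u = np.array([np.cos(theta), np.sin(theta)])
        # neck centre lies on the true axis through the head centre
        offset = axis.neck_centre - np.asarray(params.head_centre)
        lateral = abs(offset @ np.array([-u[1], u[0]]))
        assert lateral < 1e-6

    @pytest.mark.parametrize("neck_angle", [40.0, 45.0, 50.0])
    def test_recovers_generator_axis_within_one_degree(self, neck_angle, template):
        landmarks, _ = generate_hip_outline(ShapeParams(neck_axis_angle_deg=neck_angle))
        circle = fit_circle(landmarks.get(template.head_circle_range))
        axis = estimate_neck_axis(landmarks, template, circle)
        theta = np.radians(180.0 + neck_angle)
        u = np.array([np.cos(theta), np.sin(theta)])
        err = np.degrees(np.arccos(np.clip(axis.direction @ u, -1, 1)))
        assert err < 1.0

    def test_identical_neck_ranges_rejected(self, clean_hip):
        landmarks, _, _ = clean_hip
        bad = LandmarkTemplate(neck_superior_range=(41, 52), neck_inferior_range=(41, 52))
        circle = fit_circle(landmarks.get(bad.head_circle_range))
        with pytest.raises(ConfigurationError):
            estimate_neck_axis(landmarks, bad, circle)


# ---------------------------------------------------------------------------
# alpha angle
# ---------------------------------------------------------------------------


class TestAlphaAngle:
    def test_constructed_departure_at_45_degrees(self, template):
        """Contour forced off the circle at 45 deg from the neck axis."""
        landmarks, _ = generate_hip_outline(ShapeParams())  # spherical head, neck at 225
        pts = landmarks.points.copy()
        r = 25.0
        for idx, ang, rad in [(37, 168.5, r), (38, 179.9, r), (39, 180.1, 1.2 * r),
                              (40, 190.0, 1.2 * r)]:
            a = np.radians(ang)
            pts[idx - 1] = rad * np.array([np.cos(a), np.sin(a)])
        ls = LandmarkSet("constructed", pts)
        circle = fit_circle(ls.get(template.head_circle_range))
        axis = estimate_neck_axis(ls, template, circle)
        m = compute_alpha_angle(ls, template, circle, axis)
        assert m.alpha_angle_deg == pytest.approx(45.0, abs=0.5)

    def test_generator_ground_truth_recovered(self, clean_hip, template):
        landmarks, truth, _ = clean_hip
        m = measure_hip(landmarks, template)
        assert m.alpha_angle_deg == pytest.approx(truth.alpha_angle_deg, abs=1.5)

    def test_spherical_head_raises_no_departure(self, template):
        landmarks, _ = generate_hip_outline(ShapeParams(cam_present=False))
        circle = fit_circle(landmarks.get(template.head_circle_range))
        axis = estimate_neck_axis(landmarks, template, circle)
        with pytest.raises(NoDepartureError):
            compute_alpha_angle(landmarks, template, circle, axis)
        # the convenience wrapper flags instead of raising
        m = measure_hip(landmarks, template)
        assert m.departure_flag and np.isnan(m.alpha_angle_deg)

    def test_invalid_tolerance_rejected(self, clean_hip, template):
        landmarks, _, _ = clean_hip
        circle = fit_circle(landmarks.get(template.head_circle_range))
        axis = estimate_neck_axis(landmarks, template, circle)
        with pytest.raises(ConfigurationError):
            compute_alpha_angle(landmarks, template, circle, axis, departure_tolerance_frac=0.5)


# ---------------------------------------------------------------------------
# lateral centre-edge angle
# ---------------------------------------------------------------------------


class TestLCEA:
    @staticmethod
    def _with_edge(clean_hip, edge_xy):
        landmarks, _, _ = clean_hip
        pts = landmarks.points.copy()
        pts[77] = edge_xy
        return LandmarkSet("edge-case", pts)

    @pytest.mark.parametrize("edge, expected", [
        ((0.0, 5.0), 0.0),      # directly superior to the head centre
        ((-5.0, 5.0), 45.0),    # equal lateral (-x) and superior offsets
        ((5.0, 5.0), -45.0),    # medial edge -> negative angle
    ])
    def test_signed_angle_from_vertical(self, clean_hip, template, edge, expected):
        ls = self._with_edge(clean_hip, edge)
        circle = CircleFit(centre=np.zeros(2), radius=25.0, rms_radial_residual=0.0, n_points=14)
        assert compute_lcea(ls, template, circle).lcea_deg == pytest.approx(expected, abs=1e-9)

    def test_edge_at_centre_rejected(self, clean_hip, template):
        ls = self._with_edge(clean_hip, (0.0, 0.0))
        circle = CircleFit(centre=np.zeros(2), radius=25.0, rms_radial_residual=0.0, n_points=14)
        with pytest.raises(DegenerateGeometryError):
            compute_lcea(ls, template, circle)

    def test_generator_ground_truth_recovered(self, template):
        landmarks, truth = generate_hip_outline(ShapeParams(edge_angle_deg=33.7))
        m = measure_hip(landmarks, template)
        assert m.lcea_deg == pytest.approx(33.7, abs=0.5)


# ---------------------------------------------------------------------------
# minimum joint-space width
# ---------------------------------------------------------------------------


class TestMJSW:
    def test_parallel_polylines(self):
        a = np.array([[0.0, 4.0], [5.0, 4.0], [10.0, 4.0]])
        b = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert polyline_min_distance(a, b) == pytest.approx(4.0, abs=1e-12)
        assert polyline_min_distance(b, a) == pytest.approx(4.0, abs=1e-12)

    def test_touching_polylines(self):
        a = np.array([[0.0, 0.0], [5.0, 5.0]])
        b = np.array([[5.0, 5.0], [10.0, 0.0]])
        assert polyline_min_distance(a, b) == 0.0

    def test_matches_dense_sampling_oracle(self, rng):
        """Seeded random polylines agree with a dense point-sampling oracle."""
        shapely = pytest.importorskip("shapely.geometry")
        for _ in range(10):
            a = np.cumsum(rng.uniform(-1, 1, (5, 2)), axis=0)
            b = np.cumsum(rng.uniform(-1, 1, (4, 2)), axis=0) + [0.0, 5.0]
            d = polyline_min_distance(a, b)
            # dense sampling: 1000 points per segment on each polyline
            def sample(poly):
                t = np.linspace(0, 1, 1000)
                segs = [p0 + t[:, None] * (p1 - p0) for p0, p1 in zip(poly[:-1], poly[1:])]
                return np.vstack(segs)
            sa, sb = sample(a), sample(b)
            d_oracle = np.sqrt(np.min(
                ((sa[:, None, 0] - sb[None, :, 0]) ** 2
                 + (sa[:, None, 1] - sb[None, :, 1]) ** 2)))
            assert d == pytest.approx(d_oracle, abs=1e-4)
            d_shapely = shapely.LineString(a).distance(shapely.LineString(b))
            assert d == pytest.approx(d_shapely, abs=1e-9)

    def test_generator_gap_recovered_exactly(self, clean_hip, template):
        landmarks, truth, _ = clean_hip
        m = compute_mjsw(landmarks, template)
        assert m.mjsw_mm == pytest.approx(truth.mjsw_mm, abs=1e-3)

    def test_overlapping_ranges_rejected(self, clean_hip):
        landmarks, _, _ = clean_hip
        bad = LandmarkTemplate(mjsw_acetabulum_range=(25, 35), mjsw_femoral_range=(22, 31))
        with pytest.raises(ConfigurationError):
            compute_mjsw(landmarks, bad)


# ---------------------------------------------------------------------------
# scale behaviour and I/O
# ---------------------------------------------------------------------------


class TestScaleAndIO:
    def test_angles_scale_invariant_mjsw_linear(self, clean_hip, template):
        landmarks, _, _ = clean_hip
        m1 = measure_hip(landmarks, template)
        scaled = LandmarkSet("scaled", landmarks.points * 3.0)
        m2 = measure_hip(scaled, template)
        assert m2.alpha_angle_deg == pytest.approx(m1.alpha_angle_deg, abs=1e-6)
        assert m2.lcea_deg == pytest.approx(m1.lcea_deg, abs=1e-6)
        assert m2.mjsw_mm == pytest.approx(3.0 * m1.mjsw_mm, rel=1e-9)

    def test_landmark_csv_round_trip(self, clean_hip, tmp_path):
        landmarks, _, _ = clean_hip
        path = tmp_path / "landmarks.csv"
        write_landmarks_csv([landmarks], path)
        back = read_landmarks_csv(path)
        assert len(back) == 1
        assert np.allclose(back[0].points, landmarks.points, atol=1e-5)
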