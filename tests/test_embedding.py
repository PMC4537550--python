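"""Spline, sliding-window cloud, normalization and denoisers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sw1pers.embedding import (
    PointCloud,
    WindowParams,
    center_normalize,
    default_embedding_dim,
    default_window,
    fit_spline,
    mean_shift,
    moving_average,
    sliding_window_cloud,
)
from sw1pers.signals import ShapeSpec, TimeSeries, generate_shape, sample_times

TWO_PI = 2 * math.pi


class TestDefaultWindow:
    def test_m1_l1_is_pi(self):
        assert default_window(1, 1) == pytest.approx(math.pi)

    def test_large_m_approaches_pi_from_below_at_l2(self):
        w = default_window(10_000, 2)
        assert w < math.pi
        assert w == pytest.approx(math.pi, rel=1e-3)

    def test_m47_l2(self):
        assert default_window(47, 2) == pytest.approx(2 * math.pi * 47 / 96)
        assert default_window(47, 2) == pytest.approx(3.0761, abs=1e-4)

    def test_default_dim_floor(self):
        assert default_embedding_dim(25) == 51
        assert default_embedding_dim(5) == 23  # floor


class TestFitSpline:
    def test_interpolates_every_knot_and_endpoints(self, rng):
        t = np.sort(rng.uniform(0, 100, 12))
        t[0], t[-1] = 0.0, 100.0
        v = rng.standard_normal(12)
        s = TimeSeries("x", t, v)
        g = fit_spline(s)
        x = (t - t[0]) * TWO_PI / (t[-1] - t[0])
        assert np.allclose(g(x), v, atol=1e-9)
        assert g(0.0) == pytest.approx(v[0])
        assert g(TWO_PI) == pytest.approx(v[-1])

    def test_constant_series_gives_constant_function(self):
        s = TimeSeries("c", np.arange(8.0), np.full(8, 3.5))
        g = fit_spline(s)
        assert np.allclose(g(np.linspace(0, TWO_PI, 100)), 3.5, atol=1e-10)

    def test_short_series_lowers_degree(self):
        s = TimeSeries("s", np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0]))
        g = fit_spline(s)
        assert g(0.0) == pytest.approx(0.0)
        assert g(TWO_PI) == pytest.approx(0.0)

    def test_nonincreasing_times_rejected_at_construction(self):
        with pytest.raises(ValueError):
            TimeSeries("bad", np.array([0.0, 1.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            TimeSeries("bad", np.array([0.0, np.nan, 2.0]), np.zeros(3))


class TestSlidingWindowCloud:
    def test_grid_has_201_points_by_default(self, cos25):
        params = WindowParams.for_signal(25, L=2)
        cloud = sliding_window_cloud(fit_spline(cos25), params)
        assert len(cloud) == 201
        assert cloud.points.shape == (201, params.M + 1)

    def test_constant_signal_gives_identical_points(self):
        s = TimeSeries("c", np.linspace(0, 200, 10), np.full(10, 2.0))
        params = WindowParams.for_signal(10, L=2)
        cloud = sliding_window_cloud(fit_spline(s), params)
        assert np.allclose(cloud.points, 2.0, atol=1e-9)

    def test_last_window_ends_at_two_pi(self):
        params = WindowParams.for_signal(25, L=2, grid_size=50)
        starts = np.arange(51) * (TWO_PI - params.w) / 50
        assert starts[-1] + params.M * params.tau == pytest.approx(TWO_PI)

    def test_cosine_cloud_is_planar_circle(self):
        """cos(L*theta) with the natural window embeds as a planar circle."""
        M, L = 23, 2
        params = WindowParams(M=M, w=default_window(M, L), L=L)
        cloud = sliding_window_cloud(lambda x: np.cos(L * x), params)
        pts = cloud.points - cloud.points.mean(axis=0)
        sv = np.linalg.svd(pts, compute_uv=False)
        assert sv[2] / sv[0] < 1e-6  # only two dominant directions

    def test_window_at_least_two_pi_rejected(self):
        with pytest.raises(ValueError):
            WindowParams(M=10, w=TWO_PI, L=1)


class TestCenterNormalize:
    def test_unit_norm_zero_mean(self, rng):
        cloud = PointCloud(rng.standard_normal((50, 7)))
        out = center_normalize(cloud)
        assert np.allclose(np.linalg.norm(out.points, axis=1), 1.0, atol=1e-12)
        assert np.allclose(out.points.mean(axis=1), 0.0, atol=1e-12)

    def test_affine_invariance_identity(self, rng):
        x = rng.standard_normal((30, 5))
        a, c = 2.7, -4.2
        out1 = center_normalize(PointCloud(x))
        out2 = center_normalize(PointCloud(a * x + c))
        assert np.allclose(out1.points, out2.points, atol=1e-12)

    def test_degenerate_points_excluded_and_counted(self):
        pts = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.0, 0.0, 0.0]])
        out = center_normalize(PointCloud(pts))
        assert len(out) == 1
        assert out.n_degenerate == 2
        assert out.degenerate_fraction == pytest.approx(2 / 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_scale_offset_never_changes_output(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal((8, 6))
        a = float(r.uniform(0.1, 10))
        c = float(r.uniform(-100, 100))
        o1 = center_normalize(PointCloud(x)).points
        o2 = center_normalize(PointCloud(a * x + c)).points
        assert np.allclose(o1, o2, atol=1e-9)


class TestMovingAverage:
    def test_k0_is_identity(self, cos25):
        out = moving_average(cos25, 0)
        assert np.array_equal(out.values, cos25.values)

    def test_endpoints_unchanged(self):
        s = TimeSeries("s", np.arange(7.0), np.array([5.0, 1, 4, 1, 5, 9, 2.0]))
        out = moving_average(s, 2)
        assert out.values[0] == 5.0
        assert out.values[-1] == 2.0

    def test_three_point_example(self):
        s = TimeSeries("s", np.arange(3.0), np.array([0.0, 3.0, 6.0]))
        out = moving_average(s, 1)
        assert out.values.tolist() == [0.0, 3.0, 6.0]

    def test_window_span_constraint_reports_max_k(self):
        s = TimeSeries("s", np.linspace(0, 200, 25), np.zeros(25))
        params = WindowParams.for_signal(25, L=2)
        # w ~ 3.08, a third is ~1.03; sample spacing on [0,2*pi] is ~0.26
        with pytest.raises(ValueError, match="admissible k"):
            moving_average(s, 8, params)
        moving_average(s, 1, params)  # small k passes

    def test_k_too_large_for_series(self):
        s = TimeSeries("s", np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            moving_average(s, 3)


class TestMeanShift:
    def _sphere(self, pts):
        pts = pts - pts.mean(axis=1, keepdims=True)
        return PointCloud(
            pts / np.linalg.norm(pts, axis=1, keepdims=True), normalized=True
        )

    def test_isolated_point_unchanged(self, rng):
        cloud = self._sphere(rng.standard_normal((12, 9)))
        out = mean_shift(cloud, angle_threshold=1e-6)
        assert np.allclose(out.points, cloud.points, atol=1e-12)

    def test_duplicated_points_unchanged(self):
        p = np.array([[1.0, -0.5, -0.5]])
        p = p / np.linalg.norm(p)
        cloud = PointCloud(np.vstack([p, p, p]), normalized=True)
        out = mean_shift(cloud)
        assert np.allclose(out.points, cloud.points, atol=1e-12)

    def test_two_close_points_meet_at_midpoint_direction(self):
        ang = math.pi / 32
        base = np.array([1.0, -0.5, -0.5]) / np.linalg.norm([1.0, -0.5, -0.5])
        orth = np.array([0.0, 1.0, -1.0]) / np.linalg.norm([0.0, 1.0, -1.0])
        p1 = base
        p2 = math.cos(ang) * base + math.sin(ang) * orth
        mid = p1 + p2
        mid = mid / np.linalg.norm(mid)
        out = mean_shift(PointCloud(np.vstack([p1, p2]), normalized=True))
        assert np.allclose(out.points[0], mid, atol=1e-12)
        assert np.allclose(out.points[1], mid, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_contraction_max_angle_never_increases(self, seed):
        r = np.random.default_rng(seed)
        pts = r.standard_normal((40, 6))
        cloud = self._sphere(pts)

        def max_angle(c):
            cosines = np.clip(c.points @ c.points.T, -1, 1)
            return np.arccos(cosines).max()

        out = mean_shift(cloud, angle_threshold=math.pi / 8)
        assert max_angle(out) <= max_angle(cloud) + 1e-12

    def test_requires_normalized_cloud(self, rng):
        with pytest.raises(ValueError):
            mean_shift(PointCloud(rng.standard_normal((5, 3))))
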