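import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lidcontour import (
    ControlPolygon,
    DomainError,
    FitError,
    ValidationError,
    bezier_peak,
    bezier_point,
    fit_bezier,
    ray_intersection,
)
from .oracles import de_casteljau, dense_samples, grid_peak, random_arch_points

SYMMETRIC = ControlPolygon((0, 0), (0, 1), (1, 1), (1, 0))


coordinate = st.floats(-20.0, 20.0, allow_nan=False, allow_infinity=False)
point = st.tuples(coordinate, coordinate)


def polygons():
    return st.tuples(point, point, point, point).filter(
        lambda ps: abs(ps[0][0] - ps[3][0]) + abs(ps[0][1] - ps[3][1]) > 1e-6
    ).map(lambda ps: ControlPolygon(*ps))


class TestBezierPoint:
    def test_symmetric_midpoint(self):
        assert np.allclose(bezier_point(SYMMETRIC, 0.5), (0.5, 0.75))

    def test_endpoint_interpolation(self):
        curve = ControlPolygon((0, 0), (1, 2), (2, -1), (3, 1))
        assert np.allclose(bezier_point(curve, 0.0), curve.p0)
        assert np.allclose(bezier_point(curve, 1.0), curve.p3)

    def test_matches_de_casteljau(self):
        curve = ControlPolygon((0, 0), (1, 2), (2, -1), (3, 1))
        expected = de_casteljau(curve.points, 0.3)
        assert np.allclose(bezier_point(curve, 0.3), expected, atol=1e-12)

    @pytest.mark.parametrize("t", [-0.1, 1.1, 2.0])
    def test_out_of_domain(self, t):
        with pytest.raises(DomainError):
            bezier_point(SYMMETRIC, t)

    def test_degenerate_chord_rejected(self):
        with pytest.raises(ValidationError):
            ControlPolygon((1, 1), (0, 2), (3, 2), (1, 1))

    @settings(max_examples=50, derandomize=True)
    @given(polygons(), st.floats(0.0, 1.0))
    def test_convex_hull_and_de_casteljau_agreement(self, curve, t):
        """B(t) stays in the control-point convex hull and matches subdivision."""
        b = bezier_point(curve, t)
        pts = curve.points
        assert pts[:, 0].min() - 1e-9 <= b[0] <= pts[:, 0].max() + 1e-9
        assert pts[:, 1].min() - 1e-9 <= b[1] <= pts[:, 1].max() + 1e-9
        assert np.allclose(b, de_casteljau(pts, t), atol=1e-9)


class TestBezierPeak:
    def test_symmetric_arch(self):
        t, pt = bezier_peak(SYMMETRIC)
        assert t == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(pt, (0.5, 0.75))

    def test_flat_curve_tie_breaks_to_smallest_t(self):
        flat = ControlPolygon((0, 2.0), (1, 2.0), (2, 2.0), (3, 2.0))
        t, pt = bezier_peak(flat)
        assert t == 0.0
        assert pt[1] == pytest.approx(2.0)

    def test_matches_dense_grid(self):
        curve = ControlPolygon((0, 0), (2, 6), (8, 4), (12, 1))
        _, y_grid = grid_peak(curve.points)
        _, pt = bezier_peak(curve)
        assert pt[1] == pytest.approx(y_grid, abs=1e-6)

    def test_random_curves_match_grid(self, rng):
        for _ in range(25):
            curve = ControlPolygon(*random_arch_points(rng))
            _, y_grid = grid_peak(curve.points, n=200_001)
            _, pt = bezier_peak(curve)
            assert pt[1] >= y_grid - 1e-9  # grid max cannot beat the true max
            assert pt[1] == pytest.approx(y_grid, abs=1e-6)


class TestRayIntersection:
    ARCH = ControlPolygon((-0.5, 0), (-0.5, 1), (0.5, 1), (0.5, 0))

    def test_symmetric_arch_vertical(self):
        hit = ray_intersection(self.ARCH, 90.0)
        assert hit is not None
        assert hit.r == pytest.approx(0.75, abs=1e-12)
        assert hit.t == pytest.approx(0.5, abs=1e-9)

    def test_endpoint_on_axis(self):
        hit = ray_intersection(self.ARCH, 0.0)
        assert hit is not None
        assert hit.r == pytest.approx(0.5, abs=1e-12)

    def test_matches_sampling_oracle(self):
        from .oracles import ray_crossing

        curve = ControlPolygon((-12, -1), (-6, 6), (4, 7), (12, 2))
        grid = dense_samples(curve.points)
        hit = ray_intersection(curve, 45.0)
        r_oracle = ray_crossing(curve.points, 45.0, grid)
        assert hit is not None and r_oracle is not None
        assert hit.r == pytest.approx(r_oracle, abs=1e-4)

    def test_miss_is_none(self):
        # arch strictly above the pupil line: horizontal rays cannot touch it
        high = ControlPolygon((-5, 1.0), (-2, 4.0), (2, 4.0), (5, 1.0))
        assert ray_intersection(high, 0.0) is None
        assert ray_intersection(high, 180.0) is None
        assert ray_intersection(high, 90.0) is not None

    def test_vertical_ray_equals_x_root(self, rng):
        """At 90 deg, r is the curve's y where x(t) = 0 (independent x-root)."""
        for _ in range(20):
            curve = ControlPolygon(*random_arch_points(rng))
            hit = ray_intersection(curve, 90.0)
            cx = curve.power_coefficients()[:, 0]
            roots = [
                float(z.real)
                for z in np.roots(cx)
                if abs(z.imag) < 1e-9 and -1e-9 <= z.real <= 1 + 1e-9
            ]
            ys = [bezier_point(curve, min(1.0, max(0.0, t)))[1] for t in roots]
            admissible = [y for y in ys if y >= -1e-9]
            if hit is None:
                assert not admissible
            else:
                assert hit.r == pytest.approx(min(admissible), abs=1e-9)


class TestFitBezier:
    def test_exact_recovery(self):
        """Noiseless samples of a cubic are recovered exactly, any spacing."""
        curve = ControlPolygon((0, 0), (3, 8), (14, 9), (25, 2))
        pts = bezier_point(curve, np.linspace(0.0, 1.0, 50))
        fitted, rms = fit_bezier(pts)
        assert np.allclose(fitted.points, curve.points, atol=1e-6)
        assert rms < 1e-9 * np.abs(curve.points).max()

    def test_collinear_samples_give_collinear_polygon(self):
        t = np.linspace(0.0, 1.0, 30)
        pts = np.column_stack([3.0 * t, 1.5 * t + 2.0])
        fitted, rms = fit_bezier(pts)
        p = fitted.points
        cross = (p[1:, 0] - p[0, 0]) * (p[-1, 1] - p[0, 1]) - (
            p[1:, 1] - p[0, 1]
        ) * (p[-1, 0] - p[0, 0])
        assert np.all(np.abs(cross) < 1e-6)
        assert rms < 1e-9

    def test_noisy_recovery_of_peak_height(self, rng):
        """Mean |error| of the recovered peak height stays below the noise SD."""
        curve = ControlPolygon((12.5, -3), (6, 6.5), (-4, 7.0), (-12.5, -0.5))
        _, true_peak = bezier_peak(curve)
        t = np.linspace(0.0, 1.0, 200)
        clean = bezier_point(curve, t)
        errors = []
        for _ in range(40):
            noisy = clean + rng.normal(0.0, 0.05, size=clean.shape)
            fitted, _ = fit_bezier(noisy, endpoints=(curve.p0, curve.p3))
            _, peak = bezier_peak(fitted)
            errors.append(abs(peak[1] - true_peak[1]))
        assert np.mean(errors) < 0.05

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_bezier([(0, 0), (1, 1), (2, 0)])

    def test_rank_deficient(self):
        pts = np.array([[0.0, 0.0]] * 5 + [[1.0, 0.0]])
        with pytest.raises(FitError):
            fit_bezier(pts)
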