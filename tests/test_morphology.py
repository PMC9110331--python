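"""Alpha-shape metrics, diameters, scaling fits and isosbestic crossings."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from aquaclust.morphology import (ClusterShape, UndefinedShapeError,
                                  alpha_shape_metrics, distribution_crossing,
                                  fixed_slope_intercept, max_diameter,
                                  powerlaw_exponent, radius_scaling_fit,
                                  shape_factor_reference, surface_volume_fit,
                                  unwrap_cluster)
from aquaclust.synth import sample_cluster_sizes, sample_solid_surface


class TestAlphaShape:
    def test_sphere_closed_form(self):
        pts = sample_solid_surface("sphere", 10.0, 5000, seed=1)
        v, a = alpha_shape_metrics(pts, alpha_radius=10.0)
        assert v == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)
        assert a == pytest.approx(4 * np.pi * 100, rel=0.02)

    def test_cube_closed_form(self):
        pts = sample_solid_surface("cube", 10.0, 8000, seed=2)
        v, a = alpha_shape_metrics(pts, alpha_radius=50.0)
        assert v == pytest.approx(1000.0, rel=0.02)
        assert a == pytest.approx(600.0, rel=0.02)

    def test_too_few_points(self):
        with pytest.raises(UndefinedShapeError):
            alpha_shape_metrics(np.eye(3), alpha_radius=5.0)

    def test_large_alpha_converges_to_convex_hull(self):
        rng = np.random.default_rng(4)
        pts = rng.random((300, 3)) * 10
        hull = ConvexHull(pts)
        v, a = alpha_shape_metrics(pts, alpha_radius=1e6)
        assert v == pytest.approx(hull.volume, rel=1e-9)
        assert a == pytest.approx(hull.area, rel=1e-9)

    def test_tiny_alpha_keeps_nothing(self):
        rng = np.random.default_rng(5)
        pts = rng.random((50, 3)) * 10
        assert alpha_shape_metrics(pts, alpha_radius=1e-3) == (0.0, 0.0)


class TestMaxDiameter:
    def test_two_points(self):
        assert max_diameter(np.array([[0, 0, 0], [5, 0, 0.0]])) == 5.0

    def test_equilateral_triangle(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [1.5, 3**0.5 * 1.5, 0.0]])
        assert max_diameter(pts) == pytest.approx(3.0)

    def test_singleton_zero(self):
        assert max_diameter(np.array([[1.0, 2, 3]])) == 0.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.random((50, 3)) * 20
        brute = max(np.linalg.norm(a - b) for a in pts for b in pts)
        assert max_diameter(pts) == pytest.approx(brute)
        # hull shortcut path agrees with brute force as well
        big = rng.random((600, 3)) * 20
        brute_big = max(np.linalg.norm(a - b) for a in big for b in big)
        assert max_diameter(big) == pytest.approx(brute_big)


class TestUnwrap:
    def test_cluster_straddling_boundary(self, theta_455):
        """Shifting a cage across the periodic wall must not change its
        real-space geometry."""
        from aquaclust.frames import WaterFrame, wrap_positions
        from aquaclust.hbonds import detect_hbonds

        frame, _ = theta_455
        g = detect_hbonds(frame)
        mols = list(range(frame.n_molecules))
        d0 = max_diameter(unwrap_cluster(frame, mols, g))
        shift = frame.box_lengths * 0.49  # pushes the cage across the wall
        f2 = WaterFrame(wrap_positions(frame.oxygen_positions + shift,
                                       frame.box_lengths),
                        wrap_positions(frame.hydrogen_positions + shift,
                                       frame.box_lengths),
                        frame.hydrogen_owner, frame.box_lengths)
        g2 = detect_hbonds(f2)
        assert max_diameter(unwrap_cluster(f2, mols, g2)) == pytest.approx(d0)


class TestShapeFactors:
    @pytest.mark.parametrize("solid,value", [
        ("sphere", 1.57), ("cube", 1.79), ("tetrahedron", 1.97)])
    def test_reference_values(self, solid, value):
        assert shape_factor_reference(solid) == pytest.approx(value, abs=0.01)

    def test_unknown_solid(self):
        with pytest.raises(ValueError):
            shape_factor_reference("dodecahedron")

    def test_alpha_shape_path_recovers_reference(self):
        for solid in ("sphere", "cube", "tetrahedron"):
            vols, areas = [], []
            for size in (5.0, 10.0, 20.0):
                pts = sample_solid_surface(solid, size, 6000, seed=3)
                v, a = alpha_shape_metrics(pts, alpha_radius=4 * size)
                vols.append(v)
                areas.append(a)
            assert fixed_slope_intercept(vols, areas) == pytest.approx(
                shape_factor_reference(solid), abs=0.02)


class TestSurfaceVolumeFit:
    def _sphere_shapes(self, radii):
        return [ClusterShape(4 / 3 * np.pi * r**3, 4 * np.pi * r**2, 2 * r, 3.5)
                for r in radii]

    def test_ideal_spheres(self):
        fits = surface_volume_fit(self._sphere_shapes([1, 1.5, 2, 5, 8, 12]),
                                  split_volume=100.0)
        for fit in fits.values():
            assert fit.slope == pytest.approx(2 / 3, abs=1e-6)
            assert fit.intercept == pytest.approx(
                shape_factor_reference("sphere"), abs=1e-6)

    def test_sparse_regime_skipped(self):
        fits = surface_volume_fit(self._sphere_shapes([1, 1.5, 2]),
                                  split_volume=100.0)
        assert fits["large"] is None
        assert fits["small"] is not None

    def test_recovers_synthetic_line(self):
        rng = np.random.default_rng(8)
        v = np.exp(rng.uniform(0, 8, 200))
        a = np.exp(0.7 * np.log(v) + 0.5 + rng.normal(0, 1e-4, 200))
        shapes = [ClusterShape(vi, ai, 1.0, 3.5) for vi, ai in zip(v, a)]
        fits = surface_volume_fit(shapes, split_volume=100.0)
        for fit in fits.values():
            assert fit.slope == pytest.approx(0.7, abs=1e-3)
            assert fit.intercept == pytest.approx(0.5, abs=1e-2)


class TestPowerlaw:
    @pytest.mark.parametrize("tau", [2.20, 2.44])
    def test_recovery(self, tau):
        sizes = sample_cluster_sizes(tau, s_min=10, n=100_000, seed=5)
        hist: dict[int, int] = {}
        for s in sizes:
            hist[int(s)] = hist.get(int(s), 0) + 1
        assert powerlaw_exponent(hist, fit_min_size=10) == pytest.approx(
            tau, abs=0.05)

    def test_recovery_bias_across_exponents(self):
        for tau in (2.0, 2.44, 3.0):
            sizes = sample_cluster_sizes(tau, s_min=10, n=100_000, seed=11)
            hist: dict[int, int] = {}
            for s in sizes:
                hist[int(s)] = hist.get(int(s), 0) + 1
            for method in ("least-squares", "mle"):
                est = powerlaw_exponent(hist, fit_min_size=10, method=method)
                assert abs(est - tau) < 0.05, (tau, method, est)

    def test_single_size_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_exponent({7: 1000}, fit_min_size=1)


class TestRadiusScaling:
    def test_ideal_spheres_exact(self):
        shapes = [ClusterShape(4 / 3 * np.pi * r**3, 4 * np.pi * r**2,
                               2 * r, 3.5) for r in (2, 4, 8, 16)]
        dv, ds = radius_scaling_fit(shapes)
        assert dv.slope == pytest.approx(3.0, abs=1e-9)
        assert ds.slope == pytest.approx(2.0, abs=1e-9)

    def test_synthetic_exponent(self):
        r = np.linspace(2, 30, 40)
        shapes = [ClusterShape(ri**2.9, ri**2.0, 2 * ri, 3.5) for ri in r]
        dv, _ = radius_scaling_fit(shapes)
        assert dv.slope == pytest.approx(2.9, abs=1e-9)

    def test_single_shape_rejected(self):
        with pytest.raises(ValueError):
            radius_scaling_fit([ClusterShape(10, 10, 4, 3.5)])


class TestDimensionalScaling:
    def test_rescaling_points_scales_metrics(self):
        pts = sample_solid_surface("sphere", 5.0, 4000, seed=9)
        v1, a1 = alpha_shape_metrics(pts, alpha_radius=20.0)
        s = 3.0
        v2, a2 = alpha_shape_metrics(pts * s, alpha_radius=20.0 * s)
        assert v2 == pytest.approx(s**3 * v1, rel=1e-9)
        assert a2 == pytest.approx(s**2 * a1, rel=1e-9)
        assert max_diameter(pts * s) == pytest.approx(s * max_diameter(pts))


class TestCrossing:
    def test_two_gaussians_cross_at_midpoint(self):
        x = np.linspace(-4, 6, 1001)
        g1 = np.exp(-x**2 / 2)
        g2 = np.exp(-(x - 2)**2 / 2)
        crossings = distribution_crossing(x, g1, g2, smooth_window=1)
        assert len(crossings) == 1
        assert crossings[0].location == pytest.approx(1.0, abs=1e-6)
        assert crossings[0].bracket[0] <= 1.0 <= crossings[0].bracket[1]

    def test_identical_distributions_none(self):
        x = np.linspace(0, 10, 100)
        d = np.exp(-x)
        assert distribution_crossing(x, d, d) == []

    def test_constant_factor_none(self):
        x = np.linspace(0, 10, 100)
        d = np.exp(-x)
        assert distribution_crossing(x, d, 2 * d) == []
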