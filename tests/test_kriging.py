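"""Relative-risk transform, semivariograms, ordinary kriging."""

import numpy as np
import pytest

from trostar.kriging import (
    SpatialRRSummary,
    Variogram,
    _model_gamma,
    empirical_variogram,
    fit_variogram,
    krige_points,
    ordinary_krige,
    spatial_rr,
)
from trostar.model import PosteriorDraws
from trostar.records import SchoolRecord


def _draws_with_f(f_mat, ids=None):
    n, k = np.asarray(f_mat).shape
    ids = ids or [f"S{i}" for i in range(k)]
    return PosteriorDraws(
        alpha=np.zeros(n), beta=np.empty((n, 0)), gamma=np.empty((n, 0)),
        f=np.asarray(f_mat, dtype=float), tau2=np.ones(n),
        beta_names=[], gamma_names=[], school_ids=ids,
    )


def _schools(k):
    return [
        SchoolRecord(f"S{i}", float(i), float(i % 3), 1, 80.0, 5e4, 15.0, 10)
        for i in range(k)
    ]


class TestSpatialRR:
    def test_zero_field_gives_unit_relative_risk(self):
        rr = spatial_rr(_draws_with_f(np.zeros((50, 3))), _schools(3))
        assert all(s.rr_mean == pytest.approx(1.0) for s in rr)

    def test_constant_log2_field(self):
        rr = spatial_rr(_draws_with_f(np.full((50, 2), np.log(2.0))), _schools(2))
        for s in rr:
            assert (s.rr_mean, s.rr_low, s.rr_high) == (
                pytest.approx(2.0), pytest.approx(2.0), pytest.approx(2.0),
            )

    def test_lognormal_mean_closed_form(self, rng):
        sd = 0.25
        f = rng.standard_normal((100_000, 1)) * sd
        rr = spatial_rr(_draws_with_f(f), _schools(1))
        assert rr[0].rr_mean == pytest.approx(np.exp(sd**2 / 2), rel=0.01)


class TestEmpiricalVariogram:
    def test_single_pair_definition(self):
        vg = empirical_variogram(
            [(0.0, 0.0, 1.0), (1.0, 0.0, 3.0)], n_bins=1, max_dist_frac=1.0
        )
        assert vg.gamma_hat.tolist() == [2.0]  # (1/2) * (3-1)^2
        assert vg.pair_counts.tolist() == [1]

    def test_constant_field_is_degenerate_zero(self, rng):
        pts = rng.uniform(0, 10, size=(12, 2))
        vg = empirical_variogram([(x, y, 5.5) for x, y in pts])
        np.testing.assert_allclose(vg.gamma_hat, 0.0, atol=1e-25)
        assert vg.degenerate

    def test_binned_estimator_matches_double_loop_oracle(self, rng):
        pts = rng.uniform(0, 50, size=(100, 2))
        vals = np.sin(pts[:, 0] / 7.0) + rng.standard_normal(100)
        n_bins, frac = 8, 0.5
        vg = empirical_variogram(
            [(x, y, v) for (x, y), v in zip(pts, vals)],
            n_bins=n_bins, max_dist_frac=frac,
        )
        # brute force over all pairs
        dmax = max(
            np.hypot(*(pts[i] - pts[j]))
            for i in range(100) for j in range(i + 1, 100)
        )
        edges = np.linspace(0, frac * dmax, n_bins + 1)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for i in range(100):
            for j in range(i + 1, 100):
                h = np.hypot(*(pts[i] - pts[j]))
                for b in range(n_bins):
                    lo, hi = edges[b], edges[b + 1]
                    ok = (h >= lo) if b == 0 else (h > lo)
                    if ok and h <= hi:
                        sums[b] += (vals[i] - vals[j]) ** 2
                        counts[b] += 1
        keep = counts > 0
        np.testing.assert_allclose(
            vg.gamma_hat, sums[keep] / (2 * counts[keep]), atol=1e-12
        )
        np.testing.assert_array_equal(vg.pair_counts, counts[keep])


class TestFitVariogram:
    def test_noiseless_exponential_recovery(self):
        h = np.linspace(2.0, 40.0, 12)
        g = _model_gamma(h, "exponential", 0.0, 1.0, 10.0)
        vg = Variogram(bin_centers=h, gamma_hat=g, pair_counts=np.full(12, 40))
        fit = fit_variogram(vg)
        assert fit.nugget == pytest.approx(0.0, abs=1e-4)
        assert fit.partial_sill == pytest.approx(1.0, abs=1e-4)
        assert fit.range_param == pytest.approx(10.0, abs=1e-4)

    def test_pure_nugget_when_no_spatial_structure(self, rng):
        pts = rng.uniform(0, 50, size=(60, 2))
        vals = rng.standard_normal(60)  # spatially unstructured
        vg = fit_variogram(
            empirical_variogram([(x, y, v) for (x, y), v in zip(pts, vals)])
        )
        assert vg.partial_sill <= 0.25 * (vg.nugget + vg.partial_sill)

    def test_distance_scaling_equivariance(self):
        h = np.linspace(1.0, 30.0, 10)
        g = _model_gamma(h, "exponential", 0.1, 2.0, 8.0)
        counts = np.full(10, 25)
        f1 = fit_variogram(Variogram(bin_centers=h, gamma_hat=g, pair_counts=counts))
        f2 = fit_variogram(
            Variogram(bin_centers=3.0 * h, gamma_hat=g, pair_counts=counts)
        )
        assert f2.range_param == pytest.approx(3.0 * f1.range_param, rel=1e-6)
        assert f2.nugget == pytest.approx(f1.nugget, abs=1e-6)

    def test_spherical_model_supported(self):
        h = np.linspace(1.0, 30.0, 10)
        g = _model_gamma(h, "spherical", 0.05, 1.5, 20.0)
        fit = fit_variogram(
            Variogram(bin_centers=h, gamma_hat=g, pair_counts=np.full(10, 25),
                      model="spherical")
        )
        assert fit.range_param == pytest.approx(20.0, rel=1e-3)


@pytest.fixture()
def fitted_vg():
    return Variogram(
        bin_centers=np.linspace(1, 30, 10),
        gamma_hat=np.zeros(10), pair_counts=np.ones(10, dtype=int),
        nugget=0.0, partial_sill=1.0, range_param=10.0,
    )


class TestOrdinaryKriging:
    def test_exact_interpolation_at_data_points_with_zero_nugget(self, fitted_vg, rng):
        pts = rng.uniform(0, 30, size=(20, 2))
        vals = rng.standard_normal(20)
        points = [(x, y, v) for (x, y), v in zip(pts, vals)]
        preds, kvars = krige_points(points, fitted_vg, [tuple(p) for p in pts])
        np.testing.assert_allclose(preds, vals, atol=1e-8)
        np.testing.assert_allclose(kvars, 0.0, atol=1e-8)

    def test_weights_sum_to_one_everywhere(self, fitted_vg, rng):
        pts = rng.uniform(0, 30, size=(15, 2))
        vals = rng.standard_normal(15)
        points = [(x, y, v) for (x, y), v in zip(pts, vals)]
        targets = [tuple(t) for t in rng.uniform(-5, 35, size=(50, 2))]
        _, _, wts = krige_points(points, fitted_vg, targets, return_weights=True)
        np.testing.assert_allclose(wts.sum(axis=1), 1.0, atol=1e-10)
        surface = ordinary_krige(points, fitted_vg, grid_res=25)
        assert surface.max_weight_sum_error <= 1e-10

    def test_two_point_system_matches_direct_linear_solve(self, fitted_vg):
        points = [(0.0, 0.0, 1.0), (10.0, 0.0, 3.0)]
        target = (4.0, 2.0)
        preds, kvars, wts = krige_points(
            points, fitted_vg, [target], return_weights=True
        )
        # independent 3x3 solve of the ordinary kriging equations
        def gamma(h):
            return 1.0 * (1.0 - np.exp(-h / 10.0)) if h > 0 else 0.0

        g12 = gamma(10.0)
        A = np.array([[1e-12, g12, 1.0], [g12, 1e-12, 1.0], [1.0, 1.0, 0.0]])
        b = np.array([gamma(np.hypot(4, 2)), gamma(np.hypot(6, 2)), 1.0])
        sol = np.linalg.solve(A, b)
        np.testing.assert_allclose(wts[0], sol[:2], atol=1e-12)
        assert preds[0] == pytest.approx(sol[0] * 1.0 + sol[1] * 3.0, abs=1e-12)
        assert kvars[0] == pytest.approx(b[:2] @ sol[:2] + sol[2], abs=1e-12)

    def test_constant_field_surface_is_constant(self, rng):
        pts = rng.uniform(0, 20, size=(10, 2))
        points = [(x, y, np.log(2.0)) for x, y in pts]
        vg = fit_variogram(empirical_variogram(points))
        surface = ordinary_krige(points, vg, grid_res=20)
        inb = surface.in_bounds()
        np.testing.assert_allclose(surface.rr[inb], 2.0, atol=1e-12)
        np.testing.assert_allclose(surface.krig_var[inb], 0.0, atol=1e-12)

    def test_surface_invariant_to_point_relabelling(self, fitted_vg, rng):
        pts = rng.uniform(0, 20, size=(12, 2))
        vals = rng.standard_normal(12)
        points = [(x, y, v) for (x, y), v in zip(pts, vals)]
        perm = rng.permutation(12)
        shuffled = [points[i] for i in perm]
        s1 = ordinary_krige(points, fitted_vg, grid_res=15)
        s2 = ordinary_krige(shuffled, fitted_vg, grid_res=15)
        np.testing.assert_allclose(s1.rr, s2.rr, atol=1e-9, equal_nan=True)

    def test_hotspots_shrink_as_threshold_rises(self, fitted_vg, rng):
        pts = rng.uniform(0, 20, size=(12, 2))
        vals = rng.standard_normal(12)
        points = [(x, y, v) for (x, y), v in zip(pts, vals)]
        counts = [
            ordinary_krige(points, fitted_vg, grid_res=20, threshold=t).hotspot.sum()
            for t in (0.8, 1.0, 1.3)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_duplicate_points_rejected(self, fitted_vg):
        pts = [(0.0, 0.0, 1.0), (1.0, 1.0, 2.0), (1.0, 1.0, 3.0)]
        with pytest.raises(ValueError, match="duplicate"):
            ordinary_krige(pts, fitted_vg, grid_res=5)

    def test_rr_positive_inside_boundary(self, fitted_vg, rng):
        pts = rng.uniform(0, 20, size=(12, 2))
        vals = rng.standard_normal(12)
        points = [(x, y, v) for (x, y), v in zip(pts, vals)]
        surface = ordinary_krige(points, fitted_vg, grid_res=20)
        inb = surface.in_bounds()
        assert inb.any()
        assert np.all(surface.rr[inb] > 0)
        assert np.all(surface.krig_var[inb] >= 0)
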