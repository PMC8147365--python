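"""DDFT core: energy functionals, cluster-number selection, boundaries."""

import numpy as np
import pytest

from fallwatch import ddft
from fallwatch.errors import ParameterError, UndefinedPotentialError

TWO_PI_SQ = 2.0 * np.pi**2


def brute_force_pedf(queries, data, rho, delta=1e-9):
    """Independent O(N^2) double-loop oracle for the potential density."""
    queries = np.atleast_2d(queries)
    out = np.zeros(len(queries))
    for j, q in enumerate(queries):
        total = 0.0
        for ri, p in zip(np.atleast_2d(data), rho):
            dist = float(np.sqrt(((q - ri) ** 2).sum()))
            if dist > delta:
                total += p / dist
        out[j] = 0.5 * total
    return out


class TestKedf:
    @pytest.mark.parametrize("rho, expected", [
        (0.0, 0.0),
        (1.0, TWO_PI_SQ),
        (0.5, np.pi**2),
    ])
    def test_direct_substitution(self, rho, expected):
        assert ddft.kedf(np.array([rho]))[0] == pytest.approx(expected)

    def test_negative_density_rejected(self):
        with pytest.raises(ParameterError):
            ddft.kedf(np.array([-0.1]))


class TestPedf:
    def test_single_point_at_unit_distance(self):
        u = ddft.pedf(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]),
                      np.array([1.0]))
        assert u[0] == pytest.approx(0.5)

    def test_two_points_hand_sum(self):
        data = np.array([[1.0, 0.0], [2.0, 0.0]])
        u = ddft.pedf(np.array([[0.0, 0.0]]), data, np.array([1.0, 1.0]))
        assert u[0] == pytest.approx(0.75)

    def test_far_query_decays_monotonically(self):
        data = np.random.default_rng(0).standard_normal((50, 2))
        rho = np.full(50, 0.02)
        dists = np.array([5.0, 20.0, 100.0, 1000.0])
        queries = np.column_stack([dists, np.zeros(4)])
        u = ddft.pedf(queries, data, rho)
        assert np.all(np.diff(u) < 0) and u[-1] < 1e-3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((200, 2))
        rho = rng.uniform(0.01, 1.0, size=200)
        queries = rng.standard_normal((40, 2))
        fast = ddft.pedf(queries, data, rho)
        slow = brute_force_pedf(queries, data, rho)
        assert np.abs(fast - slow).max() < 1e-10

    def test_self_term_excluded_on_data(self):
        data = np.array([[0.0, 0.0], [1.0, 0.0]])
        rho = np.array([1.0, 1.0])
        u = ddft.pedf(data, data, rho)
        assert np.allclose(u, [0.5, 0.5])  # only the other point contributes

    def test_all_points_coincident_with_query(self):
        data = np.zeros((5, 2))
        with pytest.raises(UndefinedPotentialError):
            ddft.pedf(np.array([[0.0, 0.0]]), data, np.ones(5))

    def test_scaling_coordinates_scales_potential_inversely(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((30, 2))
        rho = rng.uniform(0.1, 1.0, size=30)
        q = rng.standard_normal((10, 2))
        s = 3.7
        u1 = ddft.pedf(q, data, rho)
        u2 = ddft.pedf(s * q, s * data, rho)
        assert np.allclose(u2, u1 / s)


class TestAdaptiveGamma:
    @pytest.mark.parametrize("u_mean, t_mean, expected", [
        (2.0, 1.0, 1.0),
        (3.0, 3.0, 0.5),
    ])
    def test_half_ratio_of_means(self, u_mean, t_mean, expected):
        t = np.full(10, t_mean)
        u = np.full(10, u_mean)
        assert ddft.adaptive_gamma(t, u) == pytest.approx(expected)

    def test_defining_identity_holds(self):
        rng = np.random.default_rng(3)
        t, u = rng.uniform(0.1, 2, 100), rng.uniform(0.1, 2, 100)
        g = ddft.adaptive_gamma(t, u)
        assert g**2 * t.mean() == pytest.approx(0.5 * g * u.mean(), rel=1e-12)

    def test_zero_kinetic_energy_rejected(self):
        with pytest.raises(ParameterError):
            ddft.adaptive_gamma(np.zeros(5), np.ones(5))


class TestFitDensity:
    def test_recovers_standard_normal(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((2000, 2))
        model = ddft.fit_density(pts, K=1, seed=0)
        se = 1.0 / np.sqrt(2000)
        assert np.abs(model.means[0]).max() < 3 * se
        assert np.abs(model.covariances[0] - np.eye(2)).max() < 0.1

    def test_deterministic_given_seed(self, two_cluster_points):
        a = ddft.fit_density(two_cluster_points, K=2, seed=5)
        b = ddft.fit_density(two_cluster_points, K=2, seed=5)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)

    def test_near_degenerate_k_survives_with_floor(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [3.0, 1.0],
                        [0.5, 0.5]])
        model = ddft.fit_density(pts, K=4, seed=0, n_init=1)
        for c in model.covariances:
            assert np.linalg.eigvalsh(c).min() >= ddft.COV_FLOOR * (1 - 1e-12)

    @pytest.mark.parametrize("K", [0, -1, 10])
    def test_invalid_k_rejected(self, K):
        pts = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ParameterError):
            ddft.fit_density(pts, K=K, seed=0)

    def test_pdf_integrates_to_one(self, two_cluster_points):
        model = ddft.fit_density(two_cluster_points, K=2, seed=0)
        grid = ddft.GridSpec(-8, 16, -8, 16, resolution=400)
        rho = model.pdf(grid.mesh())
        dx, dy = grid.cell
        assert rho.sum() * dx * dy == pytest.approx(1.0, abs=1e-3)


class TestEnergySurfaces:
    @pytest.fixture(scope="class")
    def surfaces(self, two_cluster_points):
        model = ddft.fit_density(two_cluster_points, K=2, seed=0)
        return ddft.energy_surfaces(model, two_cluster_points)

    def test_kedf_identity(self, surfaces):
        assert np.abs(surfaces.t - TWO_PI_SQ * surfaces.rho).max() < 1e-10

    def test_sum_and_difference_identities(self, surfaces):
        s = surfaces
        assert np.abs((s.H + s.L) - 2 * s.gamma**2 * s.t).max() < 1e-10
        assert np.abs((s.H - s.L) - 2 * s.gamma * s.u).max() < 1e-10

    def test_mean_hamiltonian_is_minus_three_mean_lagrangian(self, surfaces):
        # substituting gamma = <u>/(2<t>) gives <H> = 3/4 <u>^2/<t> = -3<L>
        mH, mL = surfaces.H.mean(), surfaces.L.mean()
        assert mH == pytest.approx(-3.0 * mL, rel=1e-8)
        expected = 0.75 * surfaces.u.mean() ** 2 / surfaces.t.mean()
        assert mH == pytest.approx(expected, rel=1e-8)

    def test_gamma_comes_from_data_not_grid(self, two_cluster_points):
        model = ddft.fit_density(two_cluster_points, K=2, seed=0)
        on_data = ddft.energy_surfaces(model, two_cluster_points)
        grid = ddft.GridSpec.from_points(two_cluster_points, resolution=40)
        on_grid = ddft.energy_surfaces(model, two_cluster_points,
                                       eval_points=grid.mesh())
        assert on_grid.gamma == on_data.gamma


class TestClusterNumberSelection:
    def test_hand_evaluated_turning_point(self):
        # first gap 6; later gaps <= 0.1 <= 0.05 * 6
        k, stable = ddft.select_cluster_number(
            np.array([10.0, 4.0, 3.9, 3.85, 3.84]), eps=0.05)
        assert k == 2 and stable

    def test_flat_curve_selects_one(self):
        k, stable = ddft.select_cluster_number(np.full(5, 7.0))
        assert k == 1 and stable

    def test_never_stabilizing_curve_returns_kmax_with_warning(self):
        curve = np.array([10.0, 8.0, 6.0, 4.0, 2.0])
        with pytest.warns(UserWarning):
            k, stable = ddft.select_cluster_number(curve, eps=0.05)
        assert k == 5 and not stable

    def test_too_short_curve_rejected(self):
        with pytest.raises(ParameterError):
            ddft.select_cluster_number(np.array([1.0, 2.0]))

    def test_two_separated_clusters_select_two(self, two_cluster_points):
        curve = ddft.hamiltonian_curve(two_cluster_points, K_max=5, seed=0)
        assert curve.selected_K == 2
        gaps = np.abs(np.diff(curve.mean_H))
        assert gaps[0] > 5 * gaps[1:].max()

    def test_single_cluster_stabilizes_immediately(self):
        pts = np.random.default_rng(6).standard_normal((800, 2))
        curve = ddft.hamiltonian_curve(pts, K_max=4, seed=0)
        assert curve.selected_K <= 2  # no second real cluster to find

    def test_curve_has_kmax_entries(self, two_cluster_points):
        curve = ddft.hamiltonian_curve(two_cluster_points, K_max=4, seed=1)
        assert len(curve.mean_H) == 4
        assert np.array_equal(curve.K_values, [1, 2, 3, 4])


class TestLagrangianBoundaries:
    @pytest.fixture(scope="class")
    def fitted(self, two_cluster_points):
        model = ddft.fit_density(two_cluster_points, K=2, seed=0)
        return model, two_cluster_points

    def test_each_cluster_mean_enclosed_by_a_contour(self, fitted):
        model, pts = fitted
        boundary = ddft.lagrangian_boundaries(model, pts, resolution=150)
        from matplotlib.path import Path as MplPath
        for k, mean in enumerate(model.means):
            enclosing = [c for c in boundary.contours[k]
                         if len(c) > 3 and MplPath(c).contains_point(mean)]
            assert enclosing, f"no contour encloses cluster mean {k}"

    def test_contour_vertices_lie_on_zero_level(self, fitted):
        model, pts = fitted
        boundary = ddft.lagrangian_boundaries(model, pts, resolution=150)
        L = boundary.L_grid
        cell_scale = np.abs(np.diff(L, axis=0)).max()
        for contours in boundary.contours.values():
            for c in contours:
                vals = ddft.interpolate_grid(boundary.grid, L, c)
                assert np.abs(vals).max() < 0.05 * cell_scale + 1e-9

    def test_refining_grid_moves_contours_less_than_coarse_cell(self, fitted):
        model, pts = fitted
        coarse = ddft.lagrangian_boundaries(model, pts, resolution=75)
        fine = ddft.lagrangian_boundaries(model, pts, resolution=150)
        cell = max(coarse.grid.cell)
        for k in range(model.K):
            for c in coarse.contours[k]:
                fine_pts = np.concatenate(fine.contours[k])
                # every coarse vertex has a fine vertex within one coarse cell
                d = np.sqrt(((c[:, None, :] - fine_pts[None, :, :]) ** 2
                             ).sum(-1)).min(axis=1)
                assert d.max() < cell

    def test_no_zero_crossing_warns_and_returns_empty(self, fitted):
        model, pts = fitted
        tiny = ddft.GridSpec(-0.01, 0.01, -0.01, 0.01, resolution=8)
        with pytest.warns(UserWarning):
            boundary = ddft.lagrangian_boundaries(model, pts, grid=tiny)
        assert all(len(v) == 0 for v in boundary.contours.values())

    def test_non_2d_space_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ParameterError):
            ddft.lagrangian_boundaries(model, np.zeros((10, 3)))


class TestSurfaceExport:
    def test_csv_round_trip_of_grid_surface(self, two_cluster_points, tmp_path):
        import pandas as pd
        from fallwatch import io as fio
        model = ddft.fit_density(two_cluster_points, K=2, seed=0)
        grid = ddft.GridSpec.from_points(two_cluster_points, resolution=20)
        surf = ddft.energy_surfaces(model, two_cluster_points,
                                    eval_points=grid.mesh())
        path = tmp_path / "surface.csv"
        fio.write_surface_csv(surf, path)
        table = pd.read_csv(path)
        assert list(table.columns) == ["x", "y", "rho", "t", "u", "H", "L"]
        assert len(table) == 400
        assert np.allclose(table["H"] + table["L"],
                           2 * surf.gamma**2 * table["t"])
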