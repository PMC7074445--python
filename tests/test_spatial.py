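"""Spatial networks, Moran's I, sPCA and structure tests."""

import numpy as np
import pytest

from wingcline import (
    interpolate_scores,
    knn_network,
    moran_eigenbasis,
    morans_i,
    spca,
    structure_test,
    structure_test_pair,
)
from wingcline.spatial_structure import ConnectionNetwork


def cycle_network(n, row_normalize=True):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = 1.0
        w[i, (i - 1) % n] = 1.0
    coords = np.column_stack([np.cos(2 * np.pi * np.arange(n) / n),
                              np.sin(2 * np.pi * np.arange(n) / n)])
    net = ConnectionNetwork(coords, w, False, 2)
    return net.row_normalize() if row_normalize else net


class TestKnnNetwork:
    def test_collinear_middle_linked_both_ways(self):
        coords = np.array([[40.0, -8.0], [41.0, -8.0], [42.0, -8.0]])
        net = knn_network(coords, k=1, row_normalize=False)
        assert net.weights[1, 0] == 1 and net.weights[1, 2] == 1
        assert net.weights[0, 1] == 1 and net.weights[2, 1] == 1
        assert net.weights[0, 2] == 0

    def test_k_equals_n_minus_one_complete(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 6), rng.uniform(-9, -1, 6)])
        net = knn_network(coords, k=5, row_normalize=False)
        off = net.weights[~np.eye(6, dtype=bool)]
        assert np.all(off == 1.0)

    def test_row_normalized_rows_sum_to_one(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 20), rng.uniform(-9, -1, 20)])
        net = knn_network(coords, k=4, row_normalize=True)
        np.testing.assert_allclose(net.weights.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(net.weights) == 0)

    def test_duplicate_coordinates_warn(self):
        coords = np.array([[40.0, -8.0], [40.0, -8.0], [41.0, -8.0], [42.0, -8.0]])
        with pytest.warns(RuntimeWarning, match="duplicate"):
            knn_network(coords, k=1)


class TestMoransI:
    def test_alternating_cycle_equals_minus_one(self):
        net = cycle_network(6)
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        # direct-summation oracle
        z = x - x.mean()
        w = net.weights
        oracle = 6 / w.sum() * (z @ w @ z) / (z @ z)
        assert oracle == pytest.approx(-1.0, abs=1e-12)
        assert morans_i(x, net) == pytest.approx(-1.0, abs=1e-12)

    def test_eigenvector_identity(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 15), rng.uniform(-9, -1, 15)])
        net = knn_network(coords, k=3)
        basis = moran_eigenbasis(net)
        n = net.n_nodes
        for j in (0, 5, n - 2):
            expected = n * basis.eigenvalues[j] / net.weights.sum()
            assert morans_i(basis.vectors[:, j], net) == pytest.approx(expected, abs=1e-10)

    def test_constant_x_raises(self):
        net = cycle_network(6)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(6), net)


class TestMoranEigenbasis:
    def test_orthonormal_and_orthogonal_to_constant(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 12), rng.uniform(-9, -1, 12)])
        basis = moran_eigenbasis(knn_network(coords, k=3))
        v = basis.vectors
        np.testing.assert_allclose(v.T @ v, np.eye(11), atol=1e-10)
        np.testing.assert_allclose(v.sum(axis=0), 0.0, atol=1e-10)

    def test_path_graph_vector_count(self):
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        net = ConnectionNetwork(np.column_stack([np.arange(4.0), np.zeros(4)]), w, False, 1)
        basis = moran_eigenbasis(net)
        assert basis.vectors.shape == (4, 3)

    def test_morans_i_monotone_in_eigenvalue_order(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 10), rng.uniform(-9, -1, 10)])
        basis = moran_eigenbasis(knn_network(coords, k=3))
        assert np.all(np.diff(basis.morans_i_of_vector) <= 1e-12)


class TestSpca:
    def test_single_variable_closed_form(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 20), rng.uniform(-9, -1, 20)])
        net = knn_network(coords, k=4)
        x = rng.normal(0, 1, (20, 1))
        res = spca(x, net)
        expected = x[:, 0].var() * morans_i(x[:, 0], net)
        assert res.eigenvalues[0] == pytest.approx(expected, abs=1e-10)

    def test_leading_eigenvalue_dominates_rayleigh_quotients(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 25), rng.uniform(-9, -1, 25)])
        net = knn_network(coords, k=5)
        x = rng.normal(0, 1, (25, 6))
        res = spca(x, net)
        xc = x - x.mean(axis=0)
        l = net.weights
        h = xc.T @ (l + l.T) @ xc / (2 * 25)
        for _ in range(1000):
            v = rng.normal(0, 1, 6)
            v /= np.linalg.norm(v)
            assert res.eigenvalues[0] >= v @ h @ v - 1e-10

    def test_eigenvalue_equals_variance_times_moran(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 30), rng.uniform(-9, -1, 30)])
        net = knn_network(coords, k=5)
        x = rng.normal(0, 1, (30, 5))
        res = spca(x, net)
        for a in range(5):
            prod = res.variance_per_axis[a] * res.morans_i_per_axis[a]
            assert res.eigenvalues[a] == pytest.approx(prod, abs=1e-8)

    def test_eigenvalue_sum_equals_trace(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 30), rng.uniform(-9, -1, 30)])
        net = knn_network(coords, k=5)
        x = rng.normal(0, 1, (30, 5))
        res = spca(x, net)
        xc = x - x.mean(axis=0)
        l = net.row_normalize().weights
        h = xc.T @ (l + l.T) @ xc / (2 * 30)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(h), abs=1e-8)

    def test_relabeling_invariance(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 18), rng.uniform(-9, -1, 18)])
        x = rng.normal(0, 1, (18, 4))
        perm = rng.permutation(18)
        e1 = spca(x, knn_network(coords, k=4)).eigenvalues
        e2 = spca(x[perm], knn_network(coords[perm], k=4)).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-10)

    def test_zero_variance_column_dropped_with_warning(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 15), rng.uniform(-9, -1, 15)])
        net = knn_network(coords, k=3)
        x = np.column_stack([rng.normal(0, 1, 15), np.full(15, 7.0)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = spca(x, net)
        assert res.axis_loadings.shape[0] == 1


class TestStructureTest:
    def test_planted_eigenvector_reaches_minimal_p(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 40), rng.uniform(-9, -1, 40)])
        net = knn_network(coords, k=5)
        basis = moran_eigenbasis(net)
        u = basis.vectors[:, 0]  # most positively autocorrelated pattern
        x = np.column_stack([u + rng.normal(0, 0.01, 40) for _ in range(5)])
        res = structure_test(x, net, kind="global", nperm=199, rng_seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_observed_stat_bounded_and_p_floor(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 30), rng.uniform(-9, -1, 30)])
        net = knn_network(coords, k=4)
        x = rng.normal(0, 1, (30, 6))
        g, l = structure_test_pair(x, net, nperm=99, rng_seed=3)
        for res in (g, l):
            assert 0.0 <= res.observed_max_t <= 1.0
            assert res.p_value >= 1 / 100
            assert np.all((res.permuted_max_t >= 0) & (res.permuted_max_t <= 1))

    def test_p_value_matches_estimator_definition(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 25), rng.uniform(-9, -1, 25)])
        net = knn_network(coords, k=4)
        x = rng.normal(0, 1, (25, 4))
        res = structure_test(x, net, kind="local", nperm=199, rng_seed=5)
        b = np.count_nonzero(res.permuted_max_t >= res.observed_max_t)
        assert res.p_value == (1 + b) / (1 + 199)

    def test_missing_sign_class_raises(self, rng):
        # complete graph: the centered weight operator has no positive
        # eigenvalue, so there are no global (positive-I) eigenvectors
        coords = np.column_stack([rng.uniform(37, 43, 8), rng.uniform(-9, -1, 8)])
        net = knn_network(coords, k=7)
        x = rng.normal(0, 1, (8, 3))
        with pytest.raises(ValueError, match="sign class"):
            structure_test(x, net, kind="global", nperm=99, rng_seed=1)

    def test_seed_required(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 20), rng.uniform(-9, -1, 20)])
        net = knn_network(coords, k=4)
        with pytest.raises(ValueError, match="seed"):
            structure_test(rng.normal(0, 1, (20, 3)), net, kind="global", nperm=199)


class TestInterpolation:
    def test_constant_scores_give_constant_grid(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 10), rng.uniform(-9, -1, 10)])
        _, _, grid = interpolate_scores(np.full(10, 2.5), coords, (20, 20))
        inside = grid[~np.isnan(grid)]
        assert inside.size > 0
        np.testing.assert_allclose(inside, 2.5, atol=1e-10)

    def test_exact_at_sample_locations(self):
        coords = np.array([[37.0, -9.0], [37.0, -1.0], [43.0, -9.0], [43.0, -1.0]])
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        lat, lon, grid = interpolate_scores(scores, coords, (3, 3))
        # corners of the grid coincide with the samples
        assert grid[0, 0] == pytest.approx(1.0)
        assert grid[0, 2] == pytest.approx(2.0)
        assert grid[2, 0] == pytest.approx(3.0)
        assert grid[2, 2] == pytest.approx(4.0)

    def test_matches_direct_idw_oracle(self, rng):
        coords = np.column_stack([rng.uniform(37, 43, 8), rng.uniform(-9, -1, 8)])
        scores = rng.normal(0, 1, 8)
        lat, lon, grid = interpolate_scores(scores, coords, (15, 15))
        cells = [(i, j) for i in range(15) for j in range(15) if not np.isnan(grid[i, j])]
        pick = [cells[i] for i in rng.choice(len(cells), 10, replace=False)]
        for i, j in pick:
            p = np.array([lat[i], lon[j]])
            d = np.linalg.norm(coords - p, axis=1)
            if d.min() < 1e-12:
                expected = scores[d.argmin()]
            else:
                w = 1 / d**2
                expected = (w @ scores) / w.sum()
            assert grid[i, j] == pytest.approx(expected, abs=1e-10)

    def test_outside_hull_masked(self):
        coords = np.array([[37.0, -9.0], [37.0, -1.0], [43.0, -5.0]])  # triangle
        _, _, grid = interpolate_scores(np.array([1.0, 2.0, 3.0]), coords, (25, 25))
        assert np.isnan(grid).any()
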