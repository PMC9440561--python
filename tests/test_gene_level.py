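import numpy as np
import pytest

from mdimpute import (
    build_network,
    build_pseudocells,
    csn_statistic,
    gene_correlations,
    predict_gene_level,
)
from mdimpute.gene_level import _z_from_counts, csn_z_matrix
from mdimpute.state_spaces import partition_cells


class TestPseudocells:
    def test_two_cell_mean(self):
        X = np.array([[2.0, 4.0]])
        part = partition_cells(np.arange(2), 2)
        assert build_pseudocells(X, part)[0, 0] == 3.0

    def test_all_zero_gene(self):
        X = np.zeros((1, 9))
        part = partition_cells(np.arange(9), 3)
        np.testing.assert_array_equal(build_pseudocells(X, part), np.zeros((1, 3)))

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.gamma(2.0, 1.0, size=(6, 9))
        part = partition_cells(np.arange(9), 3)
        got = build_pseudocells(X, part)
        for s, blk in enumerate(part.blocks):
            for i in range(6):
                assert got[i, s] == pytest.approx(np.mean(X[i, blk]), abs=1e-12)
        # pseudo-cell values stay inside the per-space value range
        for s, blk in enumerate(part.blocks):
            assert np.all(got[:, s] >= X[:, blk].min(axis=1))
            assert np.all(got[:, s] <= X[:, blk].max(axis=1))


class TestCsnStatistic:
    def test_observed_equals_expected_gives_zero(self):
        # n=100, n_x=n_y=10, n_xy=1: numerator 100*1 - 100 = 0
        assert _z_from_counts(100, 10, 10, 1) == 0.0

    def test_identical_genes_maximal_z(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=100)
        Xbar = np.vstack([v, v])
        z = csn_statistic(Xbar, 40, 0, 1, 0.1)
        bx = np.abs(v - v[40])
        k = int(np.ceil(0.1 * 100))
        n_x = int((bx <= np.partition(bx, k - 1)[k - 1]).sum())
        assert z == pytest.approx(_z_from_counts(100, n_x, n_x, n_x))
        # the identical-gene z is the maximum attainable for this (n, n_x)
        assert z > 2.326

    def test_null_mean_and_variance(self):
        # Independent genes: variance near 1. The mean carries a small
        # positive bias because the centering pseudo-cell always occupies
        # both boxes (n_xy >= 1 by construction); at S=200, fraction 0.2
        # the bias is about +0.29 and vanishes as the box count grows.
        rng = np.random.default_rng(2)
        S = 200
        zs = []
        for _ in range(500):
            x = rng.uniform(size=S)
            y = rng.uniform(size=S)
            s = int(rng.integers(S))
            zs.append(csn_statistic(np.vstack([x, y]), s, 0, 1, 0.2))
        zs = np.asarray(zs)
        assert 0.0 < zs.mean() < 0.35
        assert 0.7 < zs.var() < 1.3

    def test_too_few_pseudocells_rejected(self):
        Xbar = np.random.default_rng(0).normal(size=(2, 5))
        with pytest.raises(ValueError, match="correlation fallback"):
            csn_statistic(Xbar, 0, 0, 1, 0.1)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(3)
        Xbar = rng.normal(size=(5, 30))
        Z = csn_z_matrix(Xbar, 7, 0.2)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                assert Z[i, j] == pytest.approx(
                    csn_statistic(Xbar, 7, i, j, 0.2), abs=1e-10)
        np.testing.assert_allclose(Z, Z.T, atol=1e-10)


class TestBuildNetwork:
    def test_duplicated_gene_pair_linked(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=100)
        Xbar = np.vstack([v, v + 1.0])    # same shape, shifted level
        adj = build_network(Xbar, 50)
        assert adj[0, 1] and adj[1, 0]

    def test_independent_genes_edge_rate_bounded(self):
        rng = np.random.default_rng(5)
        S, alpha = 100, 0.01
        hits = 0
        n_pairs = 500
        for _ in range(n_pairs):
            Xbar = rng.normal(size=(2, S))
            s = int(rng.integers(S))
            hits += bool(build_network(Xbar, s, alpha=alpha)[0, 1])
        assert hits / n_pairs <= 3 * alpha

    def test_power_exceeds_false_rate(self):
        # dependence must be detected far above the null edge rate
        rng = np.random.default_rng(6)
        S = 100
        null_hits = dep_hits = 0
        for _ in range(200):
            x = rng.normal(size=S)
            y_dep = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=S)
            y_null = rng.normal(size=S)
            s = int(rng.integers(S))
            dep_hits += bool(build_network(np.vstack([x, y_dep]), s)[0, 1])
            null_hits += bool(build_network(np.vstack([x, y_null]), s)[0, 1])
        assert dep_hits >= 10 * max(null_hits, 1)

    def test_zero_variance_gene_has_no_edges(self):
        rng = np.random.default_rng(7)
        Xbar = np.vstack([np.full(50, 2.0), rng.normal(size=50)])
        adj = build_network(Xbar, 10)
        assert not adj.any()

    def test_no_self_edges_and_symmetry(self):
        rng = np.random.default_rng(8)
        Xbar = rng.normal(size=(6, 40))
        adj = build_network(Xbar, 3)
        assert not np.diag(adj).any()
        np.testing.assert_array_equal(adj, adj.T)

    def test_small_S_correlation_fallback(self, caplog):
        import logging
        v = np.arange(5.0)
        Xbar = np.vstack([v, 2 * v + 1, np.array([3, 1, 4, 1, 5.0])])
        with caplog.at_level(logging.WARNING):
            adj = build_network(Xbar, 0)
        assert adj[0, 1]                      # perfectly correlated pair
        assert any("Pearson" in r.message for r in caplog.records)


class TestGeneCorrelations:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(9)
        Xs = rng.normal(size=(3, 5))
        R = gene_correlations(Xs)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_negation_minus_one(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        R = gene_correlations(np.vstack([v, -v]))
        assert R[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_pearson_oracle(self):
        rng = np.random.default_rng(10)
        Xs = rng.gamma(2.0, 1.0, size=(4, 5))
        R = gene_correlations(Xs)
        for i in range(4):
            for j in range(4):
                a, b = Xs[i] - Xs[i].mean(), Xs[j] - Xs[j].mean()
                expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
                assert R[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_becomes_zero(self):
        Xs = np.vstack([np.full(5, 2.0), np.arange(5.0)])
        R = gene_correlations(Xs)
        assert R[0, 1] == 0.0 and R[0, 0] == 0.0


class TestPredictGeneLevel:
    def test_singleton_neighborhood_copies_neighbor(self):
        Xs = np.array([[1.0, 2.0], [5.0, 6.0]])
        adj = np.array([[False, True], [True, False]])
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        C = np.zeros_like(Xs)
        G, fb = predict_gene_level(Xs, adj, R, C)
        np.testing.assert_allclose(G[0], Xs[1])
        np.testing.assert_allclose(G[1], Xs[0])
        assert not fb.any()

    def test_empty_neighborhood_falls_back_to_cell_level(self):
        Xs = np.array([[1.0, 2.0], [5.0, 6.0]])
        adj = np.zeros((2, 2), dtype=bool)
        R = np.eye(2)
        C = np.array([[9.0, 9.0], [8.0, 8.0]])
        G, fb = predict_gene_level(Xs, adj, R, C)
        np.testing.assert_array_equal(G, C)
        assert fb.all()

    def test_weighted_mean_oracle(self):
        # neighbors with |r| = (1.0, 0.5), values (3, 6): g = 4
        Xs = np.array([[0.0], [3.0], [6.0]])
        adj = np.array([[False, True, True],
                        [True, False, False],
                        [True, False, False]])
        R = np.array([[1.0, 1.0, -0.5],
                      [1.0, 1.0, 0.0],
                      [-0.5, 0.0, 1.0]])
        G, fb = predict_gene_level(Xs, adj, R, np.zeros_like(Xs))
        assert G[0, 0] == pytest.approx((1.0 * 3 + 0.5 * 6) / 1.5)
        assert G[0, 0] == pytest.approx(4.0)

    def test_predictions_within_neighbor_range(self):
        rng = np.random.default_rng(11)
        Xs = rng.gamma(2.0, 1.0, size=(6, 4))
        R = gene_correlations(Xs)
        adj = np.abs(R) > 0.2
        np.fill_diagonal(adj, False)
        G, fb = predict_gene_level(Xs, adj, R, np.zeros_like(Xs))
        for i in range(6):
            if fb[i]:
                continue
            nbrs = Xs[adj[i]]
            assert np.all(G[i] >= nbrs.min(axis=0) - 1e-12)
            assert np.all(G[i] <= nbrs.max(axis=0) + 1e-12)
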