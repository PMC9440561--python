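import itertools

import numpy as np
import pytest

from mdimpute import (
    ExpressionMatrix,
    build_mst,
    cluster_cells,
    log_transform,
    normalize_cpm,
    order_cells,
    reduce_dims,
    simulate_trajectory,
)
from mdimpute.metrics import kendall_tau
from mdimpute.pseudotime import main_path, _project_onto_polyline


def _log_matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(values, [f"g{i}" for i in range(values.shape[0])],
                            [f"c{j}" for j in range(values.shape[1])],
                            layer="log")


class TestReduceDims:
    def test_rank_one_input_explained_by_first_component(self):
        t = np.linspace(0, 1, 10)
        values = np.outer([1.0, 2.0, 3.0], t) + 5.0
        scores = reduce_dims(_log_matrix(values), 2)
        assert np.var(scores[:, 0]) > 0
        assert np.var(scores[:, 1]) == pytest.approx(0, abs=1e-12)

    def test_score_variance_non_increasing(self):
        rng = np.random.default_rng(0)
        m = _log_matrix(rng.gamma(2.0, 2.0, size=(12, 15)))
        scores = reduce_dims(m, 5)
        v = np.var(scores, axis=0)
        assert np.all(np.diff(v) <= 1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.normal(5.0, 1.0, size=(5, 4)) ** 2
        m = _log_matrix(values)
        scores = reduce_dims(m, 3)
        # oracle: eigendecomposition of the cell-covariance matrix
        data = values.T - values.T.mean(axis=0)
        cov = data.T @ data
        w, v = np.linalg.eigh(cov)
        idx = np.argsort(w)[::-1][:3]
        oracle = data @ v[:, idx]
        for c in range(3):
            # orientation-free comparison
            err = min(np.max(np.abs(scores[:, c] - oracle[:, c])),
                      np.max(np.abs(scores[:, c] + oracle[:, c])))
            assert err < 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            reduce_dims(_log_matrix(np.full((4, 5), 3.0)), 2)


class TestClusterCells:
    def test_three_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [50, 0], [0, 50.0]])
        truth = np.repeat([0, 1, 2], 30)
        scores = centers[truth] + rng.normal(0, 0.5, size=(90, 2))
        labels, cc = cluster_cells(scores, seed=0)
        assert len(np.unique(labels)) == 3
        # same partition up to relabelling
        for g in range(3):
            assert len(np.unique(labels[truth == g])) == 1

    def test_two_cells_forced_singletons(self):
        scores = np.array([[0.0, 0.0], [10.0, 0.0]])
        labels, centers = cluster_cells(scores, k_min=2, seed=0)
        assert sorted(labels) == [0, 1]
        assert centers.shape[0] == 2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(40, 3))
        l1, c1 = cluster_cells(scores, seed=7)
        l2, c2 = cluster_cells(scores, seed=7)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(c1, c2)


class TestBuildMst:
    def test_collinear_chain(self):
        edges = build_mst(np.array([[0.0], [1.0], [2.0]]))
        assert sorted(edges) == [(0, 1), (1, 2)]

    def test_single_center(self):
        assert build_mst(np.array([[1.0, 2.0]])) == []

    def test_total_weight_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        centers = rng.normal(size=(6, 2))
        edges = build_mst(centers)
        weight = sum(np.linalg.norm(centers[i] - centers[j]) for i, j in edges)
        # oracle: enumerate all spanning trees among all edge subsets
        all_edges = list(itertools.combinations(range(6), 2))
        best = np.inf
        for subset in itertools.combinations(all_edges, 5):
            # spanning check via union-find
            parent = list(range(6))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            ok = True
            for a, b in subset:
                ra, rb = find(a), find(b)
                if ra == rb:
                    ok = False
                    break
                parent[rb] = ra
            if ok:
                w = sum(np.linalg.norm(centers[i] - centers[j])
                        for i, j in subset)
                best = min(best, w)
        assert weight == pytest.approx(best, abs=1e-8)


class TestOrderCells:
    def test_line_ordering_matches_position_rank(self):
        # cells at distinct positions along a straight line in gene space
        pos = np.array([0.9, 0.1, 0.5, 0.3, 0.7, 0.05, 0.95, 0.6, 0.2, 0.4,
                        0.8, 0.15, 0.65, 0.35, 0.55])
        values = np.outer([1.0, 2.0, 0.5], pos) * 10
        m = _log_matrix(values)
        res = order_cells(m, seed=0)
        expected = np.argsort(pos)
        assert (np.array_equal(res.order, expected)
                or np.array_equal(res.order, expected[::-1]))

    def test_trajectory_recovery(self):
        ds = simulate_trajectory(n_genes=500, n_cells=200, seed=11)
        X = log_transform(normalize_cpm(ds.observed_matrix()))
        res = order_cells(X, seed=11)
        tau = kendall_tau(res.ranks, ds.true_time)
        assert abs(tau) >= 0.8

    def test_order_is_permutation_and_mst_spans(self):
        ds = simulate_trajectory(n_genes=80, n_cells=60, seed=2)
        X = log_transform(normalize_cpm(ds.observed_matrix()))
        res = order_cells(X, seed=2)
        assert np.array_equal(np.sort(res.order), np.arange(60))
        n_clusters = res.centers.shape[0]
        assert len(res.mst_edges) == n_clusters - 1
        seen = set()
        for i, j in res.mst_edges:
            seen.update((i, j))
        assert seen == set(range(n_clusters))
        # main path is a simple path in the MST
        edge_set = {frozenset(e) for e in res.mst_edges}
        assert len(set(res.main_path)) == len(res.main_path)
        for a, b in zip(res.main_path, res.main_path[1:]):
            assert frozenset((a, b)) in edge_set

    def test_reversed_path_reverses_order(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(30, 2))
        centers = np.array([[-3.0, 0.0], [0.0, 0.2], [3.0, -0.1]])
        fwd = _project_onto_polyline(scores, centers)
        rev = _project_onto_polyline(scores, centers[::-1])
        assert np.array_equal(np.argsort(fwd), np.argsort(rev)[::-1])

    def test_user_supplied_ordering_bypasses_inference(self, toy_counts):
        X = log_transform(normalize_cpm(toy_counts))
        wanted = list(reversed(X.cell_ids))
        res = order_cells(X, order=wanted)
        assert [X.cell_ids[i] for i in res.order] == wanted

    def test_main_path_is_diameter(self):
        # star with one long arm: diameter passes through the hub
        centers = np.array([[0, 0], [1, 0], [0, 1.0], [2, 0], [3, 0]])
        edges = build_mst(centers)
        path = main_path(centers, edges)
        # 2 - 0 - 1 - 3 - 4 spans five nodes and is the unique diameter
        assert len(path) == 5
        assert {path[0], path[-1]} == {2, 4}
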