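"""Cluster-based MST pseudo-time ordering of cells.

Cells are embedded by PCA, grouped with a Gaussian mixture (model size
chosen by BIC), a minimum spanning tree is built over the cluster centers,
and every cell is projected onto the polyline through the centers of the
tree's diameter path. The arc-length position along that polyline is the
cell's pseudo-time; its rank defines the reordering that downstream
state-space construction consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .matrix_io import ExpressionMatrix

__all__ = [
    "PseudotimeResult",
    "reduce_dims",
    "cluster_cells",
    "build_mst",
    "main_path",
    "order_cells",
]


@dataclass
class PseudotimeResult:
    """A linear ordering of cells along an inferred trajectory.

    ``order[t]`` is the original index of the cell with pseudo-time rank
    ``t``; applying it to the cell axis yields the reordered matrix.
    """

    order: np.ndarray
    cluster_labels: np.ndarray
    centers: np.ndarray
    mst_edges: list
    main_path: list
    seed: int = 0
    positions: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        j = self.order.size
        if not np.array_equal(np.sort(self.order), np.arange(j)):
            raise ValueError("order is not a permutation of cell indices")

    @property
    def ranks(self) -> np.ndarray:
        """Pseudo-time rank of each cell in original index order."""
        ranks = np.empty_like(self.order)
        ranks[self.order] = np.arange(self.order.size)
        return ranks

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        ids = cell_ids if cell_ids is not None else [str(i) for i in range(self.order.size)]
        return pd.DataFrame({"cell_id": [ids[i] for i in self.order],
                             "rank": np.arange(self.order.size)})


def reduce_dims(m: ExpressionMatrix, n_components: int) -> np.ndarray:
    """PCA scores of the cells (J × n_components), sign-stabilised.

    Components are ordered by decreasing explained variance and each
    component's sign is fixed so that its largest-magnitude gene loading is
    positive, making the embedding deterministic.
    """
    if n_components < 1 or n_components > min(m.n_genes, m.n_cells):
        raise ValueError("n_components must be in [1, min(n_genes, n_cells)]")
    data = m.values.T  # cells × genes
    if np.allclose(data, data[0], atol=1e-12):
        raise ValueError("cannot reduce a constant matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    for c in range(n_components):
        loading = pca.components_[c]
        top = int(np.argmax(np.abs(loading)))
        if loading[top] < 0:
            scores[:, c] = -scores[:, c]
    return scores


def cluster_cells(scores: np.ndarray, k_min: int = 2, k_max: int = 9,
                  seed: int = 0):
    """Gaussian-mixture clustering with BIC model selection over k.

    Fits a full-covariance mixture for every k in ``[k_min, min(k_max,
    J-1)]`` (at least ``k_min``) and keeps the lowest-BIC model. Returns
    ``(labels, centers)`` with centers the mixture means in score space.
    """
    scores = np.asarray(scores, dtype=float)
    j = scores.shape[0]
    if j < 2:
        raise ValueError("need at least 2 cells to cluster")
    if j < k_min:
        raise ValueError(f"J={j} < k_min={k_min}")
    k_hi = max(k_min, min(k_max, j - 1))
    best = None
    for k in range(k_min, k_hi + 1):
        try:
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 n_init=3, random_state=seed, reg_covar=1e-6)
            gm.fit(scores)
            bic = gm.bic(scores)
        except ValueError:
            continue
        if best is None or bic < best[0]:
            best = (bic, gm)
    if best is None:
        raise ValueError("no mixture model could be fitted")
    gm = best[1]
    labels = gm.predict(scores)
    # drop empty components so centers match realised clusters
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    labels = np.array([remap[l] for l in labels])
    centers = gm.means_[used]
    return labels, centers


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(centers: np.ndarray) -> list:
    """Minimum spanning tree over cluster centers (Euclidean distance).

    Kruskal with edges sorted by (weight, i, j) so equal-weight ties break
    lexicographically. Returns a list of ``(i, j)`` pairs with ``i < j``.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k = centers.shape[0]
    if k < 1:
        raise ValueError("need at least one center")
    if k == 1:
        return []
    dists = cdist(centers, centers)
    edges = sorted((dists[i, j], i, j) for i in range(k) for j in range(i + 1, k))
    uf = _UnionFind(k)
    mst = []
    for w, i, j in edges:
        if uf.union(i, j):
            mst.append((i, j))
            if len(mst) == k - 1:
                break
    return mst


def main_path(centers: np.ndarray, mst_edges: list) -> list:
    """Diameter path of the MST: longest by edge count, ties by total
    Euclidean length, then by smallest starting cluster index."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k = centers.shape[0]
    if k == 1:
        return [0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i, j in mst_edges:
        g.add_edge(i, j, weight=float(np.linalg.norm(centers[i] - centers[j])))
    best_key, best_path = None, None
    for u in range(k):
        for v in range(k):
            if u == v:
                continue
            path = nx.shortest_path(g, u, v)  # unique path in a tree
            length = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
            key = (-(len(path) - 1), -length, path[0], path[-1])
            if best_key is None or key < best_key:
                best_key, best_path = key, path
    return list(best_path)


def _project_onto_polyline(scores: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's orthogonal projection onto the
    polyline (nearest segment; earlier segment wins ties).

    The first and last segments extend beyond their outer endpoints, so
    cells past the extreme cluster centers keep their relative order
    instead of collapsing onto the polyline ends.
    """
    j = scores.shape[0]
    if polyline.shape[0] == 1:
        return np.zeros(j)
    seg_starts = polyline[:-1]
    seg_vecs = polyline[1:] - polyline[:-1]
    seg_lens = np.linalg.norm(seg_vecs, axis=1)
    cumlen = np.concatenate([[0.0], np.cumsum(seg_lens)])
    n_segs = seg_starts.shape[0]
    best_d2 = np.full(j, np.inf)
    best_pos = np.zeros(j)
    for s in range(n_segs):
        v = seg_vecs[s]
        denom = seg_lens[s] ** 2
        if denom == 0:
            t = np.zeros(j)
        else:
            t = (scores - seg_starts[s]) @ v / denom
            lo = -np.inf if s == 0 else 0.0
            hi = np.inf if s == n_segs - 1 else 1.0
            t = np.clip(t, lo, hi)
        proj = seg_starts[s] + t[:, None] * v
        d2 = np.sum((scores - proj) ** 2, axis=1)
        better = d2 < best_d2 - 1e-15
        best_d2[better] = d2[better]
        best_pos[better] = cumlen[s] + t[better] * seg_lens[s]
    return best_pos


def order_cells(m: ExpressionMatrix, n_components: int = None,
                k_min: int = 2, k_max: int = 9, seed: int = 0,
                order: list = None) -> PseudotimeResult:
    """Infer a pseudo-time ordering of the cells of ``m``.

    A user-supplied ``order`` (list of cell ids, earliest first) bypasses
    inference entirely, so any external pseudo-time can be plugged in.

    The inferred path orientation is fixed deterministically: the
    lowest-index cell of the path's first cluster must fall in the earlier
    half of the ordering, otherwise the path is reversed.
    """
    j = m.n_cells
    if order is not None:
        idx = {c: i for i, c in enumerate(m.cell_ids)}
        if len(order) != j or set(order) != set(m.cell_ids):
            raise ValueError("user ordering must list every cell id exactly once")
        perm = np.array([idx[c] for c in order], dtype=int)
        return PseudotimeResult(perm, np.zeros(j, dtype=int),
                                np.zeros((1, 1)), [], [0], seed=seed,
                                positions=np.arange(j, dtype=float))
    if n_components is None:
        n_components = max(2, min(20, j - 1, m.n_genes - 1))
    n_components = min(n_components, m.n_genes, j)
    scores = reduce_dims(m, n_components)
    labels, centers = cluster_cells(scores, k_min=k_min, k_max=k_max, seed=seed)
    edges = build_mst(centers)
    path = main_path(centers, edges)

    def _order_along(path_):
        pos = _project_onto_polyline(scores, centers[np.asarray(path_)])
        perm = np.lexsort((np.arange(j), pos))
        return perm, pos

    perm, pos = _order_along(path)
    first_cluster_cells = np.flatnonzero(labels == path[0])
    if first_cluster_cells.size:
        anchor = int(first_cluster_cells.min())
        rank = int(np.flatnonzero(perm == anchor)[0])
        if rank > (j - 1) / 2:
            path = path[::-1]
            perm, pos = _order_along(path)
    return PseudotimeResult(perm, labels, centers, edges, list(path),
                            seed=seed, positions=pos)
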