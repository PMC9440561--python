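"""Cell-level prediction: adaptive Gaussian-kernel smoothing within a space.

Every entry is predicted from the *other* cells of its state space with
weights ``k_jj' = exp(-d_jj'^2 / sigma_j^2)``, where ``sigma_j`` is the
mean distance from cell j to the other in-space cells. The kernel width
therefore adapts to the local cell density, and the prediction for a cell
never uses the cell's own values.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .state_spaces import StatePartition

__all__ = [
    "cell_distances",
    "adaptive_kernel",
    "predict_cell_level",
    "cell_level_matrix",
]


def cell_distances(Xs: np.ndarray) -> np.ndarray:
    """Euclidean distances between the cells (columns) of a space submatrix."""
    Xs = np.asarray(Xs, dtype=float)
    if Xs.shape[1] < 2:
        raise ValueError("a space needs at least 2 cells")
    d = cdist(Xs.T, Xs.T)
    np.fill_diagonal(d, 0.0)
    return d


def adaptive_kernel(D: np.ndarray) -> np.ndarray:
    """Row-adaptive Gaussian kernel weights from a distance matrix.

    Row j uses width ``sigma_j`` = mean off-diagonal distance of row j.
    ``sigma_j = 0`` only happens for exact duplicate cells; the kernel then
    degenerates to the indicator of zero distance (the Gaussian's limit).
    K is generally not symmetric because sigma varies by row.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    off = D.sum(axis=1) / (n - 1)
    K = np.empty_like(D)
    pos = off > 0
    if pos.any():
        K[pos] = np.exp(-(D[pos] ** 2) / (off[pos, None] ** 2))
    if (~pos).any():
        K[~pos] = (D[~pos] == 0).astype(float)
    return K


def predict_cell_level(Xs: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Weighted average over the other in-space cells, per cell.

    ``c_{.,j} = sum_{j' != j} k_jj' x_{.,j'} / sum_{j' != j} k_jj'``. The
    denominator is strictly positive: Gaussian weights never vanish, and
    the sigma=0 indicator kernel only occurs when all in-space distances
    are zero (all weights 1).
    """
    Xs = np.asarray(Xs, dtype=float)
    K = np.asarray(K, dtype=float)
    K0 = K.copy()
    np.fill_diagonal(K0, 0.0)
    denom = K0.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("kernel row with no usable neighbors")
    return (Xs @ K0.T) / denom


def cell_level_matrix(X_ordered: np.ndarray, partition: StatePartition):
    """Cell-level prediction matrix C for a pseudo-time-ordered matrix.

    Returns ``(C, kernels, sigmas)`` with per-space kernel matrices and the
    per-cell kernel widths, aligned to the ordered cell axis.
    """
    X_ordered = np.asarray(X_ordered, dtype=float)
    C = np.empty_like(X_ordered)
    kernels = []
    sigmas = np.empty(X_ordered.shape[1])
    for block in partition.blocks:
        Xs = X_ordered[:, block]
        D = cell_distances(Xs)
        K = adaptive_kernel(D)
        kernels.append(K)
        sigmas[block] = D.sum(axis=1) / (len(block) - 1)
        C[:, block] = predict_cell_level(Xs, K)
    return C, kernels, sigmas
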