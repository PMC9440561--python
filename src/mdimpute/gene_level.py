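"""Gene-level prediction via per-space co-expression networks.

Pseudo-cells (per-gene means over each state space) damp the effect of
dropouts on gene-to-gene association. For each space, gene pairs are
tested for statistical dependence with a cell-specific-network (CSN) style
count statistic centered at that space's pseudo-cell: with n pseudo-cells,
n_x of them inside a box around gene i's value, n_y inside gene i''s box
and n_xy inside both,

    z = (n * n_xy - n_x * n_y) / sqrt(n_x * n_y * (n - n_x) * (n - n_y) / (n - 1)).

Under independence z is asymptotically standard normal; a pair is linked
iff z clears the one-sided normal quantile for *every* box size, which
guards against purely local dependence. Each gene is then predicted as the
|Pearson|-weighted average of its network neighbors' expression in that
space; genes with no usable neighbors fall back to the cell-level
prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .state_spaces import StatePartition

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "build_pseudocells",
    "csn_statistic",
    "csn_z_matrix",
    "build_network",
    "gene_correlations",
    "predict_gene_level",
]

DEFAULT_BOX_FRACTIONS = (0.1, 0.2, 0.3)
MIN_PSEUDOCELLS = 10
SMALL_S_ABS_CORR = 0.8


@dataclass
class CoexpressionNetwork:
    """Adjacency + correlation weights of one space's gene network."""

    space: int
    adjacency: np.ndarray           # boolean, genes × genes (subset)
    R: np.ndarray                   # Pearson correlations, same shape
    gene_subset: np.ndarray         # indices into the full gene axis
    box_fractions: tuple = DEFAULT_BOX_FRACTIONS
    alpha: float = 0.01
    min_z: np.ndarray = field(default=None, repr=False)

    def edge_frame(self, gene_ids=None) -> pd.DataFrame:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        gi = self.gene_subset[ii]
        gj = self.gene_subset[jj]
        name = (lambda g: gene_ids[g]) if gene_ids is not None else str
        return pd.DataFrame({
            "space": self.space,
            "gene_i": [name(g) for g in gi],
            "gene_j": [name(g) for g in gj],
            "min_z": self.min_z[ii, jj] if self.min_z is not None else np.nan,
            "r": self.R[ii, jj],
        })


def build_pseudocells(X_ordered: np.ndarray, partition: StatePartition) -> np.ndarray:
    """Per-gene mean over each space's cells: an I × S pseudo-cell matrix."""
    X_ordered = np.asarray(X_ordered, dtype=float)
    return np.column_stack([X_ordered[:, b].mean(axis=1) for b in partition.blocks])


def _box_membership(values: np.ndarray, s: int, box_fraction: float) -> np.ndarray:
    """Boolean mask of pseudo-cells inside the box around ``values[s]``.

    The box half-width is the distance to the ``ceil(box_fraction*n)``-th
    nearest value (the center itself counts), so the box holds at least
    that many values; ties on the boundary are all included.
    """
    d = np.abs(values - values[s])
    k = math.ceil(box_fraction * values.size)
    h = np.partition(d, k - 1)[k - 1]
    return d <= h


def _z_from_counts(n: int, n_x: int, n_y: int, n_xy: int) -> float:
    if n_x in (0, n) or n_y in (0, n):
        return 0.0
    denom = math.sqrt(n_x * n_y * (n - n_x) * (n - n_y) / (n - 1))
    return (n * n_xy - n_x * n_y) / denom


def csn_statistic(Xbar: np.ndarray, s: int, i: int, i2: int,
                  box_fraction: float) -> float:
    """Dependence z-statistic for genes ``i`` and ``i2`` centered at space ``s``."""
    Xbar = np.asarray(Xbar, dtype=float)
    n = Xbar.shape[1]
    if n < MIN_PSEUDOCELLS:
        raise ValueError(
            f"only {n} pseudo-cells; the independence test needs at least "
            f"{MIN_PSEUDOCELLS} — use the correlation fallback"
        )
    if not 0 < box_fraction < 1:
        raise ValueError("box_fraction must lie in (0, 1)")
    bx = _box_membership(Xbar[i], s, box_fraction)
    by = _box_membership(Xbar[i2], s, box_fraction)
    return _z_from_counts(n, int(bx.sum()), int(by.sum()), int((bx & by).sum()))


def csn_z_matrix(Xbar: np.ndarray, s: int, box_fraction: float) -> np.ndarray:
    """All-pairs z-statistics at space ``s`` (vectorised over gene pairs)."""
    Xbar = np.asarray(Xbar, dtype=float)
    n_genes, n = Xbar.shape
    if n < MIN_PSEUDOCELLS:
        raise ValueError("too few pseudo-cells for the independence test")
    d = np.abs(Xbar - Xbar[:, [s]])
    k = math.ceil(box_fraction * n)
    h = np.partition(d, k - 1, axis=1)[:, [k - 1]]
    B = (d <= h)                      # I × n box membership
    counts = B.sum(axis=1).astype(float)
    n_xy = B.astype(float) @ B.T
    num = n * n_xy - np.outer(counts, counts)
    cn = counts * (n - counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / np.sqrt(np.outer(cn, cn) / (n - 1))
    bad = (counts == 0) | (counts == n)
    z[bad, :] = 0.0
    z[:, bad] = 0.0
    z[~np.isfinite(z)] = 0.0
    np.fill_diagonal(z, 0.0)
    return z


def build_network(Xbar: np.ndarray, s: int,
                  box_fractions=DEFAULT_BOX_FRACTIONS, alpha: float = 0.01,
                  gene_subset=None) -> np.ndarray:
    """Boolean adjacency at space ``s``: edge iff z exceeds the one-sided
    upper normal quantile for every box fraction.

    With fewer than 10 pseudo-cells the z-statistic is meaningless; the
    edge rule then falls back to |Pearson| >= 0.8 on the pseudo-cells
    (logged prominently).
    """
    Xbar = np.asarray(Xbar, dtype=float)
    if gene_subset is not None:
        Xbar = Xbar[np.asarray(gene_subset, dtype=int)]
    n_genes, n = Xbar.shape
    if n < MIN_PSEUDOCELLS:
        logger.warning(
            "only %d pseudo-cells: skipping the independence test and "
            "linking genes with |Pearson| >= %.2f on pseudo-cells",
            n, SMALL_S_ABS_CORR,
        )
        R = gene_correlations(Xbar)
        adj = np.abs(R) >= SMALL_S_ABS_CORR
        np.fill_diagonal(adj, False)
        return adj
    adj, _ = _network_with_min_z(Xbar, s, box_fractions, alpha)
    return adj


def _network_with_min_z(Xbar: np.ndarray, s: int, box_fractions, alpha: float):
    z_crit = special.ndtri(1.0 - alpha)
    adj = None
    min_z = None
    for f in box_fractions:
        z = csn_z_matrix(Xbar, s, f)
        ok = z > z_crit
        adj = ok if adj is None else (adj & ok)
        min_z = z if min_z is None else np.minimum(min_z, z)
    np.fill_diagonal(adj, False)
    return adj, min_z


def gene_correlations(Xs: np.ndarray) -> np.ndarray:
    """Pearson correlations between gene rows; undefined entries become 0."""
    Xs = np.asarray(Xs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(Xs)
    R = np.atleast_2d(R)
    R[~np.isfinite(R)] = 0.0
    return R


def predict_gene_level(Xs: np.ndarray, adjacency: np.ndarray, R: np.ndarray,
                       cell_level: np.ndarray):
    """Predict each gene from its network neighbors in one space.

    Weights are |Pearson r| restricted to neighbors (association is
    sign-agnostic and absolute weights keep the prediction a convex
    combination of neighbor values). Genes with no neighbors, or whose
    neighbor |r| weights sum to zero, fall back to the cell-level
    prediction; the returned boolean mask marks those genes.
    """
    Xs = np.asarray(Xs, dtype=float)
    W = np.abs(R) * adjacency
    np.fill_diagonal(W, 0.0)
    wsum = W.sum(axis=1)
    fallback = wsum <= 0
    G = np.array(cell_level, dtype=float, copy=True)
    if (~fallback).any():
        G[~fallback] = (W[~fallback] @ Xs) / wsum[~fallback, None]
    return G, fallback
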