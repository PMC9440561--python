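"""Evaluation statistics for imputation and ordering quality.

Pure functions: Gini coefficient of an expression vector, RMSE,
correlation-matrix distance (CMD), pseudo-temporal ordering score (POS),
tie-corrected Kendall tau, pair-counting partition indices (ARI, Jaccard,
Fowlkes–Mallows) and label accuracy (ACC).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score, fowlkes_mallows_score
from sklearn.metrics.cluster import pair_confusion_matrix

__all__ = [
    "gini",
    "rmse",
    "cmd",
    "pos_score",
    "kendall_tau",
    "clustering_indices",
    "acc",
]


def gini(values) -> float:
    """Gini coefficient, mean-difference form.

    ``G = sum_ij |y_i - y_j| / (2 n^2 ybar)``; 0 for a perfectly uniform
    vector, (n-1)/n when a single entry holds everything.
    """
    y = np.asarray(values, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("gini needs at least 2 values")
    if np.any(y < 0):
        raise ValueError("gini is defined for nonnegative values")
    total = y.sum()
    if total == 0:
        raise ValueError("gini is undefined for an all-zero vector")
    n = y.size
    ys = np.sort(y)
    # sum_ij |y_i - y_j| = 2 * sum_i (2i - n + 1) * y_(i)   (0-based i)
    abs_diff_sum = 2.0 * np.sum((2 * np.arange(n) - n + 1) * ys)
    return float(abs_diff_sum / (2.0 * n * total))


def rmse(y, y_hat) -> float:
    """Root mean squared difference between two equal-length vectors."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size or y.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def cmd(R1, R2) -> float:
    """Correlation matrix distance: ``1 - tr(R1 R2) / (||R1||_F ||R2||_F)``.

    Zero iff the matrices are proportional; at most 1.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.shape != R2.shape or R1.ndim != 2 or R1.shape[0] != R1.shape[1]:
        raise ValueError("cmd needs two square matrices of the same shape")
    n1 = np.linalg.norm(R1, "fro")
    n2 = np.linalg.norm(R2, "fro")
    if n1 == 0 or n2 == 0:
        raise ValueError("cmd is undefined for a zero matrix")
    return float(1.0 - np.sum(R1 * R2) / (n1 * n2))


def _label_ranks(labels, level_order=None) -> np.ndarray:
    labels = list(labels)
    if level_order is None:
        level_order = sorted(set(labels))
    rank = {lab: i for i, lab in enumerate(level_order)}
    missing = set(labels) - set(rank)
    if missing:
        raise ValueError(f"labels {sorted(missing)!r} absent from level order")
    return np.array([rank[lab] for lab in labels])


def pos_score(predicted_order, reference_labels, level_order=None) -> float:
    """Pseudo-temporal ordering score in [-1, 1].

    Over all cell pairs whose reference labels differ, a pair scores +1
    when the predicted ordering agrees with the label-level ordering and
    -1 when it disagrees; same-label pairs are excluded. 1 means perfectly
    label-ordered, -1 exactly reversed.
    """
    order = np.asarray(predicted_order, dtype=int)
    n = order.size
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    lev = _label_ranks(reference_labels, level_order)
    if np.unique(lev).size < 2:
        raise ValueError("pos_score needs at least two distinct label levels")
    dl = np.sign(lev[:, None] - lev[None, :])
    dr = np.sign(ranks[:, None] - ranks[None, :])
    informative = dl != 0
    agree = np.sum((dl * dr)[informative])
    return float(agree / informative.sum())


def kendall_tau(predicted, reference, level_order=None) -> float:
    """Tie-corrected Kendall tau-b between a predicted ordering (or rank
    vector) and reference values (numeric or ordered labels)."""
    x = np.asarray(predicted)
    if not np.issubdtype(np.asarray(reference).dtype, np.number):
        reference = _label_ranks(reference, level_order)
    y = np.asarray(reference, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if np.ptp(x.astype(float)) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall tau is undefined for a constant vector")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def clustering_indices(pred_labels, ref_labels):
    """(ARI, Jaccard, Fowlkes–Mallows) from the pair contingency counts."""
    pred = np.asarray(pred_labels)
    ref = np.asarray(ref_labels)
    if pred.size != ref.size:
        raise ValueError("length mismatch")
    c = pair_confusion_matrix(ref, pred)
    a = c[1, 1] / 2.0   # pairs together in both partitions
    b = c[1, 0] / 2.0   # together in ref only
    d = c[0, 1] / 2.0   # together in pred only
    denom = a + b + d
    jaccard = float(a / denom) if denom else 1.0
    ari = float(adjusted_rand_score(ref, pred))
    fm = float(fowlkes_mallows_score(ref, pred))
    return ari, jaccard, fm


def acc(ref_labels, assigned_labels) -> float:
    """Fraction of cells whose assigned label equals the reference label."""
    ref = list(ref_labels)
    got = list(assigned_labels)
    if len(ref) != len(got) or not ref:
        raise ValueError("acc needs two equal-length non-empty label lists")
    return float(sum(r == g for r, g in zip(ref, got)) / len(ref))
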