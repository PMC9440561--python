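"""Multidimensional imputation: model class, blend rule, and pipeline.

The blend combines the raw value with the cell-level and gene-level
predictions through the entry's dropout probability:

    x_hat = p * (beta/(alpha+beta) * c + alpha/(alpha+beta) * g) + (1-p) * x

with alpha = sd(C) and beta = sd(G), so the less dispersed (more stable)
prediction layer gets the larger weight. High-expression entries have
p ~ 0 and are left essentially untouched; only likely dropouts move.

:class:`ImputationModel` is the statsmodels-style entry point: build it
from a counts matrix, call :meth:`~ImputationModel.fit`, and inspect the
returned :class:`ImputationResult` (imputed matrix, alpha/beta, the C/G/P
layers, the pseudo-time ordering, per-space logistic fits, summary()).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cell_level import cell_level_matrix
from .dropout_model import dropout_probabilities, fit_logistic, zero_stats
from .gene_level import (
    _network_with_min_z,
    build_network,
    build_pseudocells,
    gene_correlations,
    predict_gene_level,
    DEFAULT_BOX_FRACTIONS,
    MIN_PSEUDOCELLS,
)
from .matrix_io import (
    ExpressionMatrix,
    filter_matrix,
    inverse_transform,
    log_transform,
    normalize_cpm,
    write_matrix,
)
from .pseudotime import PseudotimeResult, order_cells
from .state_spaces import StatePartition, compute_m, partition_cells

logger = logging.getLogger(__name__)

__all__ = ["ImputeConfig", "ImputationModel", "ImputationResult",
           "combine", "run_pipeline"]


@dataclass
class ImputeConfig:
    """Tunable parameters of the imputation pipeline.

    ``m=None`` uses the cell-number rule ``5(ceil(J/1000)+1)``;
    ``network_genes`` caps the co-expression network to the highest-
    variance genes (others fall back to the cell-level prediction);
    ``corr_on_pseudocells`` switches the gene weights R from the space's
    cells to the pseudo-cell matrix; ``per_space_weights`` computes
    alpha/beta per space instead of globally.
    """

    m: int = None
    min_last: int = 3
    theta: float = 1.0
    min_cells_per_gene: int = 0
    min_genes_per_cell: int = 0
    n_components: int = None
    k_min: int = 2
    k_max: int = 9
    box_fractions: tuple = DEFAULT_BOX_FRACTIONS
    network_alpha: float = 0.01
    network_genes: int = 2000
    corr_on_pseudocells: bool = False
    per_space_weights: bool = False
    order: list = None              # user-supplied cell ids, earliest first


def combine(X, C, G, P, fallback_mask=None, partition: StatePartition = None,
            per_space: bool = False):
    """Blend raw values with predictions through dropout probabilities.

    Returns ``(X_hat, alpha, beta)``. ``alpha``/``beta`` are the population
    standard deviations over all entries of C and G. When both are zero the
    two (constant) predictions are averaged with equal weight. With
    ``per_space=True`` the weights are computed within each partition
    block (``alpha``/``beta`` are then returned as arrays over spaces).
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    if not (X.shape == C.shape == G.shape == P.shape):
        raise ValueError("X, C, G, P must share one shape")

    def _blend(x, c, g, p):
        a = float(c.std())
        b = float(g.std())
        if a + b == 0:
            wc = wg = 0.5
        else:
            wc, wg = b / (a + b), a / (a + b)
        return p * (wc * c + wg * g) + (1.0 - p) * x, a, b

    if per_space:
        if partition is None:
            raise ValueError("per-space weights need a partition")
        X_hat = np.empty_like(X)
        alphas, betas = [], []
        for blk in partition.blocks:
            X_hat[:, blk], a, b = _blend(X[:, blk], C[:, blk], G[:, blk],
                                         P[:, blk])
            alphas.append(a)
            betas.append(b)
        return X_hat, np.array(alphas), np.array(betas)
    X_hat, a, b = _blend(X, C, G, P)
    return X_hat, a, b


@dataclass
class ImputationResult:
    """Fitted imputation with all intermediate layers, in input cell order."""

    imputed: ExpressionMatrix            # log layer
    alpha: float
    beta: float
    C: np.ndarray
    G: np.ndarray
    P: np.ndarray
    fallback_genes: np.ndarray           # genes × spaces boolean
    pseudotime: PseudotimeResult
    partition: StatePartition
    dropout_fits: pd.DataFrame
    config: ImputeConfig
    seed: int
    version: str = _pkg_version
    timings: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.imputed.values

    def to_counts(self) -> ExpressionMatrix:
        """Imputed matrix on the (CPM-scaled) count scale."""
        return inverse_transform(self.imputed)

    def save_layers(self, directory, format: str = "csv") -> None:
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ids = (self.imputed.gene_ids, self.imputed.cell_ids)
        for name, arr, layer in (("imputed", self.values, "log"),
                                 ("cell_level", self.C, "log"),
                                 ("gene_level", self.G, "log"),
                                 ("dropout_prob", self.P, "counts")):
            em = ExpressionMatrix(arr, *ids, layer=layer,
                                  theta=self.imputed.theta)
            write_matrix(em, directory / f"{name}.{format}", format)
        self.dropout_fits.to_csv(directory / "dropout_fits.csv", index=False)
        self.pseudotime.to_frame(self.imputed.cell_ids).to_csv(
            directory / "pseudotime.csv", index=False)

    def summary(self) -> str:
        lines = [
            "Multidimensional imputation results",
            "===================================",
            f"genes x cells          {self.imputed.n_genes} x {self.imputed.n_cells}",
            f"spaces (S) / per-space m  {self.partition.S} / {self.partition.m}",
            f"alpha (sd of C)        {np.mean(self.alpha):.4f}"
            + (" (mean over spaces)" if np.ndim(self.alpha) else ""),
            f"beta  (sd of G)        {np.mean(self.beta):.4f}"
            + (" (mean over spaces)" if np.ndim(self.beta) else ""),
            f"mean dropout prob      {self.P.mean():.4f}",
            f"gene-level fallback    {self.fallback_genes.mean():.1%} of gene-space pairs",
            f"zeros in input         {np.mean(self.imputed.values == 0):.1%} remain zero"
            if np.any(self.imputed.values == 0) else
            "zeros in input         all imputed to nonzero",
            "",
            "Per-space logistic dropout fits:",
            self.dropout_fits.to_string(index=False),
        ]
        return "\n".join(lines)


class ImputationModel:
    """Imputation model over a raw counts matrix.

    Parameters
    ----------
    counts : ExpressionMatrix
        Raw (or UMI) counts, genes × cells.
    config : ImputeConfig, optional
        Pipeline parameters; defaults follow the method's published rules.

    ``fit(seed)`` runs preprocessing (CPM + log2), pseudo-time ordering,
    state-space partitioning, cell-level and gene-level prediction,
    dropout-probability estimation and the final blend, returning an
    :class:`ImputationResult` aligned to the original cell order.
    """

    def __init__(self, counts: ExpressionMatrix, config: ImputeConfig = None):
        if counts.layer != "counts":
            raise ValueError("ImputationModel expects a counts-layer matrix")
        self.counts = counts
        self.config = config or ImputeConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: ImputeConfig = None) -> "ImputationModel":
        return cls(ExpressionMatrix.from_dataframe(df), config)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> ImputationResult:
        cfg = self.config
        timings = {}

        def _tick(name, t0):
            timings[name] = time.perf_counter() - t0
            logger.info("stage %-12s %.2fs", name, timings[name])
            return time.perf_counter()

        t0 = time.perf_counter()
        try:
            m0 = self.counts
            if cfg.min_cells_per_gene or cfg.min_genes_per_cell:
                m0 = filter_matrix(m0, cfg.min_cells_per_gene,
                                   cfg.min_genes_per_cell)
            X = log_transform(normalize_cpm(m0), cfg.theta)
        except Exception as e:
            raise type(e)(f"[preprocess] {e}") from e
        t0 = _tick("preprocess", t0)

        try:
            pt = order_cells(X, n_components=cfg.n_components,
                             k_min=cfg.k_min, k_max=cfg.k_max, seed=seed,
                             order=cfg.order)
        except Exception as e:
            raise type(e)(f"[pseudotime] {e}") from e
        t0 = _tick("pseudotime", t0)

        J = X.n_cells
        m = cfg.m if cfg.m is not None else compute_m(J)
        partition = partition_cells(pt.order, m, cfg.min_last)
        X_ord = X.values[:, pt.order]

        try:
            C_ord, _, _ = cell_level_matrix(X_ord, partition)
        except Exception as e:
            raise type(e)(f"[cell_level] {e}") from e
        t0 = _tick("cell_level", t0)

        try:
            G_ord, fallback = self._gene_level(X_ord, C_ord, partition)
        except Exception as e:
            raise type(e)(f"[gene_level] {e}") from e
        t0 = _tick("gene_level", t0)

        try:
            P_ord, fits = self._dropout(X_ord, partition)
        except Exception as e:
            raise type(e)(f"[dropout_model] {e}") from e
        t0 = _tick("dropout_model", t0)

        X_hat_ord, alpha, beta = combine(X_ord, C_ord, G_ord, P_ord,
                                         partition=partition,
                                         per_space=cfg.per_space_weights)
        t0 = _tick("combine", t0)

        inv = pt.order  # X_hat[:, order[t]] = X_hat_ord[:, t]
        def _restore(a):
            out = np.empty_like(a)
            out[:, inv] = a
            return out

        imputed = ExpressionMatrix(_restore(X_hat_ord), list(X.gene_ids),
                                   list(X.cell_ids), layer="log",
                                   theta=cfg.theta)
        return ImputationResult(
            imputed=imputed,
            alpha=alpha,
            beta=beta,
            C=_restore(C_ord), G=_restore(G_ord), P=_restore(P_ord),
            fallback_genes=fallback,
            pseudotime=pt, partition=partition, dropout_fits=fits,
            config=cfg, seed=seed, timings=timings,
        )

    # ------------------------------------------------------------------
    def _gene_subset(self, X_ord: np.ndarray) -> np.ndarray:
        n_genes = X_ord.shape[0]
        cap = self.config.network_genes
        if cap is None or n_genes <= cap:
            return np.arange(n_genes)
        var = X_ord.var(axis=1)
        subset = np.argsort(-var, kind="stable")[:cap]
        return np.sort(subset)

    def _gene_level(self, X_ord, C_ord, partition: StatePartition):
        cfg = self.config
        Xbar = build_pseudocells(X_ord, partition)
        subset = self._gene_subset(X_ord)
        n_genes = X_ord.shape[0]
        S = partition.S
        G = C_ord.copy()                       # genes outside the subset: g = c
        fallback = np.ones((n_genes, S), dtype=bool)
        Xbar_sub = Xbar[subset]
        for s, blk in enumerate(partition.blocks):
            Xs = X_ord[np.ix_(subset, blk)]
            adj = build_network(Xbar_sub, s, cfg.box_fractions,
                                cfg.network_alpha)
            R = gene_correlations(Xbar_sub if cfg.corr_on_pseudocells else Xs)
            Gs, fb = predict_gene_level(Xs, adj, R, C_ord[np.ix_(subset, blk)])
            G[np.ix_(subset, blk)] = Gs
            fallback[subset, s] = fb
        return G, fallback

    def _dropout(self, X_ord, partition: StatePartition):
        P = np.empty_like(X_ord)
        rows = []
        for s, blk in enumerate(partition.blocks):
            Xs = X_ord[:, blk]
            mu, z = zero_stats(Xs)
            fit = fit_logistic(mu, z)
            P[:, blk] = dropout_probabilities(Xs, fit.a, fit.b)
            rows.append(dict(space=s, a=fit.a, b=fit.b,
                             fallback=fit.fallback, converged=fit.converged,
                             resid_norm=fit.resid_norm))
        return P, pd.DataFrame(rows)


def run_pipeline(raw: ExpressionMatrix, config: ImputeConfig = None,
                 seed: int = 0) -> ImputationResult:
    """One-call pipeline: preprocess, order, partition, predict, blend."""
    return ImputationModel(raw, config).fit(seed=seed)
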