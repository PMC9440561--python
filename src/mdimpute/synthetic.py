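"""Ground-truthed synthetic scRNA-seq data with trajectory or group structure.

The generator produces negative-binomial counts around smooth latent-time
expression programs (or discrete group profiles) and then applies excess
zeros with a decreasing logistic function of the log mean count — exactly
the mechanism the dropout model assumes — so parameter recovery and
masking-recovery experiments have a known truth.

What it emulates: a single linear differentiation trajectory, gene
programs that are constant / monotone / switch-like / transient in latent
time, overdispersed counts, modest library-size variation, and
expression-dependent dropout. What it does not emulate: branching
trajectories, batch effects, ambient RNA, or empirical library-size
distributions of any particular platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .matrix_io import ExpressionMatrix

__all__ = [
    "SyntheticDataset",
    "simulate_trajectory",
    "simulate_groups",
    "mask_entries",
]

# defaults for the generative model; these are the study conditions
PROFILE_MIX = (0.4, 0.2, 0.2, 0.2)   # constant, linear, sigmoid, pulse
NB_DISPERSION = 0.3                   # var = mu + phi mu^2
DROPOUT_A = 1.5
DROPOUT_B = -1.0
LIBRARY_SD = 0.2                      # lognormal sd of cell size factors


@dataclass
class SyntheticDataset:
    """A simulated dataset with its dropout-free truth."""

    true_log: np.ndarray          # log2(CPM+1) of dropout-free counts
    true_counts: np.ndarray
    observed_counts: np.ndarray
    dropout_mask: np.ndarray      # True where a positive count was zeroed
    true_means: np.ndarray        # generating NB mean of every entry
    gen_params: dict
    true_time: np.ndarray = None
    true_labels: np.ndarray = None
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)

    def observed_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.observed_counts, self.gene_ids,
                                self.cell_ids, layer="counts")

    def true_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.true_counts, self.gene_ids,
                                self.cell_ids, layer="counts")


def _log_cpm(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("simulated dataset has an all-zero cell")
    return np.log2(counts * (1e6 / sums) + 1.0)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


def _apply_dropout(rng: np.random.Generator, counts: np.ndarray,
                   mu: np.ndarray, a: float, b: float):
    """Zero entries with probability expit(a + b*log2(mu+1)) on the count
    scale, so the fitted logistic curve has a recoverable target."""
    p = expit(a + b * np.log2(mu + 1.0))
    drop = rng.random(counts.shape) < p
    observed = np.where(drop, 0.0, counts)
    mask = drop & (counts > 0)
    return observed, mask


def _gene_profiles(rng: np.random.Generator, n_genes: int, t: np.ndarray,
                   mix) -> np.ndarray:
    """Latent-time activity f_i(t) in [0, 1] per gene."""
    kinds = rng.choice(4, size=n_genes, p=np.asarray(mix) / np.sum(mix))
    f = np.empty((n_genes, t.size))
    for i, kind in enumerate(kinds):
        if kind == 0:      # constant
            f[i] = rng.uniform(0.3, 0.7)
        elif kind == 1:    # linear, random direction
            f[i] = t if rng.random() < 0.5 else 1.0 - t
        elif kind == 2:    # switch-like
            c = rng.uniform(0.25, 0.75)
            s = rng.uniform(8.0, 20.0) * (1 if rng.random() < 0.5 else -1)
            f[i] = expit(s * (t - c))
        else:              # transient pulse
            c = rng.uniform(0.2, 0.8)
            w = rng.uniform(0.08, 0.2)
            f[i] = np.exp(-((t - c) ** 2) / (2 * w * w))
    return f


def simulate_trajectory(n_genes: int = 500, n_cells: int = 300,
                        seed: int = 0, profile_mix=PROFILE_MIX,
                        dispersion: float = NB_DISPERSION,
                        dropout_a: float = DROPOUT_A,
                        dropout_b: float = DROPOUT_B,
                        library_sd: float = LIBRARY_SD,
                        dropout: bool = True) -> SyntheticDataset:
    """Simulate cells along a latent trajectory with logistic dropout.

    Latent times are uniform on [0, 1]; gene mean-count programs mix
    constant, linear, sigmoid and transient-pulse shapes (default weights
    0.4/0.2/0.2/0.2) with lognormal baselines and amplitudes; counts are
    negative binomial; dropout zeroes entries with probability
    ``expit(a + b log2(mu+1))`` (defaults a=1.5, b=-1). Deterministic
    given ``seed``.
    """
    if n_genes < 50 or n_cells < 30:
        raise ValueError("need n_genes >= 50 and n_cells >= 30")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, n_cells)
    f = _gene_profiles(rng, n_genes, t, profile_mix)
    base = rng.lognormal(np.log(2.0), 0.5, n_genes)
    amp = rng.lognormal(np.log(20.0), 0.5, n_genes)
    lib = rng.lognormal(0.0, library_sd, n_cells)
    mu = (base[:, None] + amp[:, None] * f) * lib[None, :]
    counts = _nb_counts(rng, mu, dispersion)
    if dropout:
        observed, mask = _apply_dropout(rng, counts, mu, dropout_a, dropout_b)
    else:
        observed, mask = counts.copy(), np.zeros_like(counts, dtype=bool)
    return SyntheticDataset(
        true_log=_log_cpm(counts),
        true_counts=counts,
        observed_counts=observed,
        dropout_mask=mask,
        true_means=mu,
        true_time=t,
        gen_params=dict(n_genes=n_genes, n_cells=n_cells, seed=seed,
                        profile_mix=tuple(profile_mix), dispersion=dispersion,
                        dropout_a=dropout_a, dropout_b=dropout_b,
                        library_sd=library_sd, dropout=dropout,
                        mode="trajectory"),
        gene_ids=[f"gene{i}" for i in range(n_genes)],
        cell_ids=[f"cell{j}" for j in range(n_cells)],
    )


def simulate_groups(n_genes: int = 500, n_cells: int = 300,
                    n_groups: int = 3, de_fraction: float = 0.2,
                    lfc: float = 2.0, seed: int = 0,
                    dispersion: float = NB_DISPERSION,
                    dropout_a: float = DROPOUT_A,
                    dropout_b: float = DROPOUT_B,
                    dropout: bool = True) -> SyntheticDataset:
    """Simulate discrete cell groups with group-specific expression shifts.

    A ``de_fraction`` subset of genes is up-shifted by ``2**lfc`` in one
    randomly chosen group each; the rest is shared. Dropout as in
    :func:`simulate_trajectory`.
    """
    if n_genes < 50 or n_cells < 30:
        raise ValueError("need n_genes >= 50 and n_cells >= 30")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if not 0 < de_fraction < 1:
        raise ValueError("de_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_groups), np.diff(
        np.round(np.linspace(0, n_cells, n_groups + 1)).astype(int)))
    base = rng.lognormal(np.log(8.0), 0.8, n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_genes = rng.choice(n_genes, n_de, replace=False)
    de_group = rng.integers(0, n_groups, n_de)
    mu = np.tile(base[:, None], (1, n_cells))
    for g, grp in zip(de_genes, de_group):
        mu[g, labels == grp] *= 2.0 ** lfc
    counts = _nb_counts(rng, mu, dispersion)
    if dropout:
        observed, mask = _apply_dropout(rng, counts, mu, dropout_a, dropout_b)
    else:
        observed, mask = counts.copy(), np.zeros_like(counts, dtype=bool)
    return SyntheticDataset(
        true_log=_log_cpm(counts),
        true_counts=counts,
        observed_counts=observed,
        dropout_mask=mask,
        true_means=mu,
        true_labels=labels,
        gen_params=dict(n_genes=n_genes, n_cells=n_cells, seed=seed,
                        n_groups=n_groups, de_fraction=de_fraction, lfc=lfc,
                        dispersion=dispersion, dropout_a=dropout_a,
                        dropout_b=dropout_b, dropout=dropout, mode="groups"),
        gene_ids=[f"gene{i}" for i in range(n_genes)],
        cell_ids=[f"cell{j}" for j in range(n_cells)],
    )


def mask_entries(m: ExpressionMatrix, rate: float, seed: int = 0):
    """Zero a uniform random ``round(rate * nnz)`` of the nonzero entries.

    Returns ``(masked ExpressionMatrix, boolean mask)``; the mask marks the
    entries that were zeroed. Standard masking-recovery protocol.
    """
    if not 0 < rate < 1:
        raise ValueError("rate must lie in (0, 1)")
    nz = np.flatnonzero(m.values)
    if nz.size == 0:
        raise ValueError("matrix has no nonzero entries to mask")
    rng = np.random.default_rng(seed)
    n_mask = int(round(rate * nz.size))
    chosen = rng.choice(nz, size=n_mask, replace=False)
    values = m.values.copy()
    values.flat[chosen] = 0.0
    mask = np.zeros(m.values.shape, dtype=bool)
    mask.flat[chosen] = True
    masked = ExpressionMatrix(values, list(m.gene_ids), list(m.cell_ids),
                              layer=m.layer, theta=m.theta)
    return masked, mask
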