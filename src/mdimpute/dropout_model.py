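"""Per-space logistic dropout-probability model.

Dropout probability decreases with expression level. For every space the
per-gene mean expression mu_i and zero fraction z_i are fitted by
nonlinear least squares to the decreasing logistic curve

    z ~ 1 - 1/(1 + exp(a + b * mu)),   b <= 0,

and each entry's dropout probability is the fitted curve evaluated at its
own expression: p_ij = 1 - 1/(1 + exp(a + b * x_ij)). High expression thus
gets probability near zero and is left almost untouched by imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

__all__ = ["LogisticFit", "zero_stats", "fit_logistic", "dropout_probabilities"]

MIN_GENES = 5
_TOL = 1e-8


@dataclass
class LogisticFit:
    a: float
    b: float
    fallback: bool = False
    converged: bool = True
    resid_norm: float = 0.0


def zero_stats(Xs: np.ndarray):
    """Per-gene (mean expression, zero fraction) over one space's cells.

    Means include zero entries: they are part of the observed average
    expression of the gene in the space.
    """
    Xs = np.asarray(Xs, dtype=float)
    if Xs.ndim != 2 or Xs.shape[1] < 1:
        raise ValueError("need a genes × cells submatrix with >= 1 cell")
    mu = Xs.mean(axis=1)
    z = (Xs == 0).mean(axis=1)
    return mu, z


def _fallback_fit(z: np.ndarray) -> LogisticFit:
    zbar = float(np.clip(np.mean(z) if z.size else 0.0, 0.01, 0.99))
    return LogisticFit(a=float(logit(zbar)), b=-1.0, fallback=True,
                       converged=False)


def fit_logistic(mu, z) -> LogisticFit:
    """Least-squares fit of the decreasing logistic zero-fraction curve.

    Minimises ``sum_i (z_i - (1 - 1/(1+exp(a + b mu_i))))^2`` subject to
    ``b <= 0``, started from ``a0 = logit(clip(mean z, 0.01, 0.99))``,
    ``b0 = -1``. Degenerate inputs (fewer than 5 distinct means, constant
    zero fractions) or optimizer failure produce the flat fallback
    ``(logit(clip(mean z, 0.01, 0.99)), -1)`` instead of an error.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    ok = np.isfinite(mu) & np.isfinite(z)
    mu, z = mu[ok], z[ok]
    if np.unique(mu).size < MIN_GENES or np.ptp(z) == 0:
        return _fallback_fit(z)
    a0 = float(logit(np.clip(z.mean(), 0.01, 0.99)))

    def resid(p):
        return expit(p[0] + p[1] * mu) - z

    try:
        res = least_squares(resid, x0=[a0, -1.0],
                            bounds=([-np.inf, -np.inf], [np.inf, 0.0]),
                            ftol=_TOL, xtol=_TOL, gtol=_TOL)
    except Exception:
        return _fallback_fit(z)
    if not res.success or not np.all(np.isfinite(res.x)):
        return _fallback_fit(z)
    return LogisticFit(a=float(res.x[0]), b=float(res.x[1]),
                       fallback=False, converged=True,
                       resid_norm=float(np.linalg.norm(res.fun)))


def dropout_probabilities(Xs: np.ndarray, a: float, b: float) -> np.ndarray:
    """Elementwise ``p = 1 - 1/(1 + exp(a + b x))`` — i.e. expit(a + b x)."""
    Xs = np.asarray(Xs, dtype=float)
    return expit(a + b * Xs)
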