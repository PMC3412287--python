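"""Rubin's-rules combination of per-imputation fits.

Given M completed-data fits with estimates theta_m and variance matrices
U_m, the pooled estimate is the mean theta_bar = M^{-1} sum theta_m, and the
pooled variance is

    Sigma_M = W_bar + (1 + 1/M) B,

where W_bar is the mean of the U_m (within-imputation variance) and B the
sample covariance of the theta_m (between-imputation variance, divisor
M - 1).  Per-coefficient degrees of freedom use the classical large-sample
formula df_j = (M - 1) (1 + W_bar_jj / ((1 + 1/M) B_jj))^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PoolingError, ValidationError
from .estimators import QuasiCompleteFit


@dataclass
class PooledFit:
    """Rubin's-rules pooled estimate with variance decomposition."""

    theta: np.ndarray
    within: np.ndarray
    between: np.ndarray
    cov: np.ndarray
    df: np.ndarray
    M: int
    labels: list[str] | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def pool(fits: list[QuasiCompleteFit]) -> PooledFit:
    """Combine M >= 2 per-imputation fits by Rubin's rules."""
    if len(fits) < 2:
        raise PoolingError(f"pooling needs at least 2 fits, got {len(fits)}")
    p = len(fits[0].theta)
    for f in fits:
        if len(f.theta) != p or f.cov.shape != (p, p):
            raise ValidationError("fits have mismatched coefficient dimensions")
    M = len(fits)
    thetas = np.vstack([f.theta for f in fits])
    theta_bar = thetas.mean(axis=0)
    W_bar = np.mean([f.cov for f in fits], axis=0)
    dev = thetas - theta_bar
    B = dev.T @ dev / (M - 1)
    Sigma = W_bar + (1 + 1 / M) * B
    bjj = np.diag(B)
    wjj = np.diag(W_bar)
    with np.errstate(divide="ignore"):
        r = wjj / ((1 + 1 / M) * bjj)
    df = np.where(bjj > 0, (M - 1) * (1 + r) ** 2, np.inf)
    return PooledFit(theta_bar, W_bar, B, Sigma, df, M, labels=fits[0].labels)


def single_fit_pooled(fit: QuasiCompleteFit) -> PooledFit:
    """Wrap a single (no-imputation) fit as a PooledFit with B = 0."""
    p = len(fit.theta)
    zero = np.zeros((p, p))
    df = np.full(p, float(max(fit.residual_df, 1)))
    return PooledFit(fit.theta.copy(), fit.cov.copy(), zero, fit.cov.copy(),
                     df, M=1, labels=fit.labels)
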