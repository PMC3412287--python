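"""Weighted estimating-equation fits with sandwich variances.

The quasi-complete-data analysis fits the declared model only to included
individuals, weighting each individual's estimating-equation contribution by
W_i = 1/pi_i.  For the linear model this is weighted least squares

    theta_hat = (X' diag(W) X)^{-1} X' diag(W) Y,

with the robust (HC0-form) sandwich variance

    U_hat = A^{-1} B A^{-1},
    A = sum_i W_i x_i x_i',   B = sum_i W_i^2 e_i^2 x_i x_i',

where e_i is the residual at theta_hat.  The logistic analogue solves the
weighted score equations by damped Newton iterations, with
A = sum_i W_i v_i x_i x_i' (v_i the fitted binomial variance) and
B = sum_i W_i^2 (Y_i - p_i)^2 x_i x_i'.

``adjusted_sandwich`` additionally accounts for the estimation of the
weights by stacking the missingness-model score equations with the weighted
analysis estimating equations and taking the theta block of the joint
sandwich.  Ignoring this correction is conservative for the intercept when
weights are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import CollinearityError, EstimationError, ValidationError

RANK_RTOL = 1e-8


@dataclass
class QuasiCompleteFit:
    """Point estimate and sandwich variance from one (quasi-)complete fit."""

    theta: np.ndarray
    cov: np.ndarray
    kind: str  # "wls" | "weighted_logistic"
    weight_adjusted: bool = False
    labels: list[str] | None = None
    nobs: int = 0
    residual_df: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _check_rank(X: np.ndarray, context: str = "design") -> None:
    if X.shape[0] < X.shape[1]:
        raise CollinearityError(
            f"{context}: fewer rows ({X.shape[0]}) than columns ({X.shape[1]})"
        )
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        # name the dependent columns via the null space
        _, _, vt = np.linalg.svd(X)
        dep = np.flatnonzero(np.abs(vt[-1]) > 1e-6)
        raise CollinearityError(
            f"{context}: rank deficient; columns {dep.tolist()} are linearly dependent"
        )


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)) or np.any(W <= 0):
        raise ValidationError("weights must be positive and finite")
    return W


def wls_fit(
    Y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> QuasiCompleteFit:
    """Weighted least squares with HC0-form sandwich variance."""
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    W = np.ones(n) if W is None else _check_weights(W)
    if W.shape != (n,) or Y.shape != (n,):
        raise ValidationError("Y, X, W have inconsistent lengths")
    sw = np.sqrt(W)
    Xw = X * sw[:, None]
    _check_rank(Xw, "wls design")
    theta, *_ = np.linalg.lstsq(Xw, Y * sw, rcond=None)
    e = Y - X @ theta
    A = Xw.T @ Xw  # sum W x x'
    Ainv = np.linalg.inv(A)
    Bh = X * (W * e)[:, None]  # rows W_i e_i x_i
    B = Bh.T @ Bh  # sum W^2 e^2 x x'
    cov = Ainv @ B @ Ainv
    cov = (cov + cov.T) / 2
    return QuasiCompleteFit(theta, cov, "wls", labels=labels, nobs=n,
                            residual_df=n - p)


def weighted_logistic_fit(
    Y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray | None = None,
    labels: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
    max_halvings: int = 30,
) -> QuasiCompleteFit:
    """Weighted logistic score equations solved by damped Newton iterations."""
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not np.all((Y == 0) | (Y == 1)):
        raise ValidationError("logistic outcome must be coded 0/1")
    W = np.ones(n) if W is None else _check_weights(W)
    _check_rank(X, "logistic design")

    theta = np.zeros(p)

    def score_nll(th):
        eta = X @ th
        pr = expit(eta)
        score = X.T @ (W * (Y - pr))
        # weighted negative log-likelihood for step halving
        nll = -np.sum(W * (Y * eta - np.logaddexp(0.0, eta)))
        return score, nll, pr

    score, nll, pr = score_nll(theta)
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            break
        v = pr * (1 - pr)
        H = (X * (W * v)[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information matrix: {exc}") from exc
        lam = 1.0
        for _ in range(max_halvings):
            cand = theta + lam * step
            s2, nll2, pr2 = score_nll(cand)
            if nll2 < nll or np.max(np.abs(s2)) < np.max(np.abs(score)):
                theta, score, nll, pr = cand, s2, nll2, pr2
                break
            lam /= 2
        else:
            raise EstimationError("logistic fit: step halving failed to improve")
    else:
        raise EstimationError(
            "logistic fit did not converge (possible separation); "
            f"max |score| = {np.max(np.abs(score)):.3g}"
        )
    if np.any(pr < 1e-10) or np.any(pr > 1 - 1e-10):
        # fitted probabilities at machine bounds signal separation
        if np.max(np.abs(theta)) > 30:
            raise EstimationError("logistic fit: separation suspected (|theta| > 30)")
    v = pr * (1 - pr)
    A = (X * (W * v)[:, None]).T @ X
    Ainv = np.linalg.inv(A)
    Bh = X * (W * (Y - pr))[:, None]
    B = Bh.T @ Bh
    cov = Ainv @ B @ Ainv
    cov = (cov + cov.T) / 2
    return QuasiCompleteFit(theta, cov, "weighted_logistic", labels=labels,
                            nobs=n, residual_df=n - p)


def adjusted_sandwich(fit: QuasiCompleteFit, weightset, data, analysis_spec) -> QuasiCompleteFit:
    """Sandwich variance accounting for estimated weights.

    Stacks the missingness-model (logistic) score equations for alpha with
    the weighted analysis estimating equations for theta and returns the
    theta block of the joint sandwich.  Requires ``weightset`` to have been
    produced by :func:`ipwmi.weights.fit_missingness_model`
    (``known_weights`` False, score design retained).
    """
    from .datamodel import build_design  # local import avoids a cycle

    if weightset.known_weights:
        raise ValidationError(
            "adjusted_sandwich requires estimated weights (known_weights=False)"
        )
    if weightset.score_design is None:
        raise ValidationError("weight set carries no score design for alpha")
    if fit.kind != "wls":
        raise ValidationError("weight-adjusted sandwich implemented for WLS fits")

    Z = weightset.score_design  # N x q logistic design for the inclusion model
    g = weightset.included.astype(float)  # inclusion indicator per individual
    pi = weightset.pi_all  # fitted P(g=1 | Z) for every individual
    N, q = Z.shape

    incl = weightset.included
    X, Y = build_design(data, analysis_spec, rows=incl)
    theta = fit.theta
    p = X.shape[1]
    e = Y - X @ theta
    W = 1.0 / pi[incl]

    # stacked estimating functions U_i = (s_i^alpha, s_i^theta)
    U = np.zeros((N, q + p))
    U[:, :q] = Z * (g - pi)[:, None]
    U[incl, q:] = X * (W * e)[:, None]

    # bread A = sum_i -dU_i/d(alpha,theta)'
    A = np.zeros((q + p, q + p))
    A[:q, :q] = (Z * (pi * (1 - pi))[:, None]).T @ Z
    A[q:, q:] = (X * W[:, None]).T @ X
    # d s_theta / d alpha: W_i = 1/expit(z'alpha) so dW/dalpha = -(1-pi) W z
    dWda = -((1 - pi[incl]) * W)[:, None] * Z[incl]  # n_incl x q
    A[q:, :q] = -(X * e[:, None]).T @ dWda

    B = U.T @ U
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular joint Jacobian: {exc}") from exc
    V = Ainv @ B @ Ainv.T
    cov = V[q:, q:]
    cov = (cov + cov.T) / 2
    return QuasiCompleteFit(theta.copy(), cov, fit.kind, weight_adjusted=True,
                            labels=fit.labels, nobs=fit.nobs,
                            residual_df=fit.residual_df)
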