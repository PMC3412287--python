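import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

import statsmodels.api as sm

from ipwmi import (
    InclusionRule,
    ModelSpec,
    WeightModelSpec,
    adjusted_sandwich,
    build_design,
    fit_missingness_model,
    from_frame,
    weighted_logistic_fit,
    wls_fit,
)
from ipwmi.errors import CollinearityError, EstimationError, ValidationError
from ipwmi.weights import WeightSet


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def wls_oracle(y, X, w):
    """Solve the weighted estimating equations by generic root-finding and
    assemble the sandwich by explicit per-row loops."""
    n, p = X.shape

    def ee(theta):
        out = np.zeros(p)
        for i in range(n):
            out += w[i] * X[i] * (y[i] - X[i] @ theta)
        return out

    theta = optimize.fsolve(ee, np.zeros(p), full_output=False, xtol=1e-13)
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    for i in range(n):
        e = y[i] - X[i] @ theta
        A += w[i] * np.outer(X[i], X[i])
        B += (w[i] * e) ** 2 * np.outer(X[i], X[i])
    Ainv = np.linalg.inv(A)
    return theta, Ainv @ B @ Ainv


def logistic_oracle(y, X, w):
    n, p = X.shape

    def ee(theta):
        out = np.zeros(p)
        for i in range(n):
            out += w[i] * X[i] * (y[i] - expit(X[i] @ theta))
        return out

    theta = optimize.fsolve(ee, np.zeros(p), xtol=1e-13)
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    for i in range(n):
        pi = expit(X[i] @ theta)
        A += w[i] * pi * (1 - pi) * np.outer(X[i], X[i])
        B += (w[i] * (y[i] - pi)) ** 2 * np.outer(X[i], X[i])
    Ainv = np.linalg.inv(A)
    return theta, Ainv @ B @ Ainv


# ---------------------------------------------------------------------------
# weighted least squares
# ---------------------------------------------------------------------------

def test_wls_intercept_only_is_weighted_mean():
    fit = wls_fit(np.array([1.0, 2.0]), np.ones((2, 1)), np.array([1.0, 3.0]))
    assert fit.theta[0] == pytest.approx(1.75)


def test_wls_exact_fit_has_zero_variance(rng):
    X = np.column_stack([np.ones(10), rng.standard_normal(10)])
    theta = np.array([2.0, -1.0])
    fit = wls_fit(X @ theta, X)
    assert np.allclose(fit.theta, theta)
    assert np.allclose(fit.cov, 0.0, atol=1e-20)


def test_wls_matches_brute_force_oracle(rng):
    X = np.column_stack([np.ones(8), rng.standard_normal((8, 2))])
    y = rng.standard_normal(8)
    w = rng.uniform(0.5, 3.0, 8)
    fit = wls_fit(y, X, w)
    theta_o, cov_o = wls_oracle(y, X, w)
    assert np.allclose(fit.theta, theta_o, atol=1e-10)
    assert np.allclose(fit.cov, cov_o, atol=1e-10)


def test_unweighted_wls_equals_ols_with_hc0(rng):
    X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
    y = X @ np.array([1.0, 0.5, -0.5]) + rng.standard_normal(40)
    fit = wls_fit(y, X)
    ols = sm.OLS(y, X).fit(cov_type="HC0")
    assert np.allclose(fit.theta, ols.params, atol=1e-12)
    assert np.allclose(fit.cov, ols.cov_params(), atol=1e-12)


@pytest.mark.parametrize("c", [0.1, 2.0, 1e3])
def test_weight_scale_equivariance(rng, c):
    X = np.column_stack([np.ones(25), rng.standard_normal(25)])
    y = rng.standard_normal(25)
    w = rng.uniform(0.2, 2.0, 25)
    f1, f2 = wls_fit(y, X, w), wls_fit(y, X, c * w)
    assert np.allclose(f1.theta, f2.theta)
    assert np.allclose(f1.cov, f2.cov)


def test_wls_error_paths(rng):
    X = np.column_stack([np.ones(10), np.ones(10)])
    with pytest.raises(CollinearityError):
        wls_fit(rng.standard_normal(10), X)
    X2 = np.column_stack([np.ones(10), rng.standard_normal(10)])
    with pytest.raises(ValidationError):
        wls_fit(rng.standard_normal(10), X2, np.r_[np.ones(9), 0.0])


# ---------------------------------------------------------------------------
# weighted logistic
# ---------------------------------------------------------------------------

def test_logistic_unit_weights_match_statsmodels(rng):
    X = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
    y = (rng.random(50) < expit(X @ np.array([0.3, 1.0, -0.5]))).astype(float)
    fit = weighted_logistic_fit(y, X)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert np.allclose(fit.theta, ref.params, atol=1e-8)


def test_logistic_intercept_only_closed_form():
    y = np.array([1.0, 0, 0, 0] * 5)
    fit = weighted_logistic_fit(y, np.ones((20, 1)))
    assert fit.theta[0] == pytest.approx(np.log(1 / 3), abs=1e-9)


def test_weight_two_equals_physical_duplication(rng):
    X = np.column_stack([np.ones(30), rng.standard_normal(30)])
    y = (rng.random(30) < 0.5).astype(float)
    fit_w = weighted_logistic_fit(y, X, np.full(30, 2.0))
    fit_dup = weighted_logistic_fit(np.r_[y, y], np.vstack([X, X]))
    assert np.allclose(fit_w.theta, fit_dup.theta, atol=1e-9)


def test_weighted_logistic_matches_oracle(rng):
    X = np.column_stack([np.ones(40), rng.standard_normal(40)])
    y = (rng.random(40) < expit(X[:, 1])).astype(float)
    w = rng.uniform(0.5, 4.0, 40)
    fit = weighted_logistic_fit(y, X, w)
    theta_o, cov_o = logistic_oracle(y, X, w)
    assert np.allclose(fit.theta, theta_o, atol=1e-8)
    assert np.allclose(fit.cov, cov_o, atol=1e-8)


def test_separation_raises():
    X = np.column_stack([np.ones(10), np.r_[np.zeros(5), np.ones(5)]])
    y = np.r_[np.zeros(5), np.ones(5)]
    with pytest.raises(EstimationError):
        weighted_logistic_fit(y, X)


# ---------------------------------------------------------------------------
# weight-estimation-adjusted sandwich
# ---------------------------------------------------------------------------

def _adjusted_fixture(n=60, seed=5):
    rng = np.random.default_rng(seed)
    z = rng.integers(0, 2, n).astype(float)
    v = 1.0 + 0.5 * z + rng.standard_normal(n)
    obs = rng.random(n) < expit(0.8 - 0.9 * z)
    v = np.where(obs, v, np.nan)
    d = from_frame(pd.DataFrame({"Z": z, "V": v}),
                   roles={"Z": ("weight_predictor",)})
    rule = InclusionRule.block_complete(("V",))
    ws = fit_missingness_model(d, rule, WeightModelSpec(("Z",), "logistic"))
    spec = ModelSpec("V", ["Z"])
    X, y = build_design(d, spec, rows=ws.included)
    fit = wls_fit(y, X, ws.weights, labels=spec.column_labels)
    return d, rule, ws, spec, fit


def stacked_sandwich_oracle(d, ws, spec, fit, eps=1e-6):
    """Finite-difference bread for the stacked (alpha, theta) equations."""
    Z = ws.score_design
    g = ws.included.astype(float)
    incl = ws.included
    X, y = build_design(d, spec, rows=incl)
    q, p = Z.shape[1], X.shape[1]
    alpha_hat = ws.alpha

    def stacked(eta):
        a, t = eta[:q], eta[q:]
        pi = expit(Z @ a)
        s_alpha = Z.T @ (g - pi)
        w = 1.0 / pi[incl]
        s_theta = X.T @ (w * (y - X @ t))
        return np.r_[s_alpha, s_theta]

    eta_hat = np.r_[alpha_hat, fit.theta]
    J = np.zeros((q + p, q + p))
    for j in range(q + p):
        e = np.zeros(q + p)
        e[j] = eps
        J[:, j] = (stacked(eta_hat + e) - stacked(eta_hat - e)) / (2 * eps)
    A = -J
    # meat: per-individual stacked scores at the estimates
    pi = expit(Z @ alpha_hat)
    U = np.zeros((len(g), q + p))
    U[:, :q] = Z * (g - pi)[:, None]
    w = 1.0 / pi[incl]
    U[incl, q:] = X * (w * (y - X @ fit.theta))[:, None]
    Ainv = np.linalg.inv(A)
    V = Ainv @ (U.T @ U) @ Ainv.T
    return V[q:, q:]


def test_adjusted_sandwich_matches_finite_difference_oracle():
    d, rule, ws, spec, fit = _adjusted_fixture()
    adj = adjusted_sandwich(fit, ws, d, spec)
    oracle_cov = stacked_sandwich_oracle(d, ws, spec, fit)
    assert np.allclose(adj.cov, oracle_cov, atol=1e-6)
    assert np.allclose(adj.theta, fit.theta)


def test_adjusted_sandwich_shrinks_intercept_variance():
    # with a saturated/logistic weight model on a discrete Z, accounting for
    # weight estimation reduces the intercept variance
    d, rule, ws, spec, fit = _adjusted_fixture(n=400, seed=11)
    adj = adjusted_sandwich(fit, ws, d, spec)
    assert adj.cov[0, 0] <= fit.cov[0, 0] + 1e-12


def test_adjusted_sandwich_refuses_known_weights():
    d, rule, ws, spec, fit = _adjusted_fixture()
    known = WeightSet(ws.included, ws.pi_all, known_weights=True)
    with pytest.raises(ValidationError):
        adjusted_sandwich(fit, known, d, spec)
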