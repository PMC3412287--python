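import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipwmi import (
    InclusionRule,
    ModelSpec,
    MVNImputerSpec,
    attach_weight_terms,
    build_design,
    from_frame,
    impute_mvn_block,
    impute_regression,
    set_known_weights,
    unit_weights,
)
from ipwmi.errors import CollinearityError, DegeneracyError, ValidationError
from ipwmi.imputation import draw_regression_params

ALL = InclusionRule.all_rows()


def _outcome_missing_data(n=400, frac=0.4, seed=2):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 1.0 + 2.0 * x + rng.standard_normal(n)
    y[rng.random(n) < frac] = np.nan
    return from_frame(pd.DataFrame({"Y": y, "X": x}), roles={"Y": ("outcome",)})


SPEC_YX = ModelSpec("Y", ["X"])


def test_fully_observed_outcome_gives_identical_copies(rng):
    d = _outcome_missing_data(frac=0.0)
    ws = unit_weights(d, ALL)
    stack = impute_regression(d, ws, SPEC_YX, M=3, rng=rng)
    assert stack.M == 3
    for vals in stack.values:
        assert np.array_equal(vals, stack.values[0])
        assert np.allclose(vals, d.values)


def test_observed_cells_preserved_exactly(rng):
    d = _outcome_missing_data()
    ws = unit_weights(d, ALL)
    stack = impute_regression(d, ws, SPEC_YX, M=5, rng=rng)
    obs = ~d.mask
    for vals in stack.values:
        assert np.array_equal(vals[obs], d.values[obs])
        assert not np.isnan(vals).any()


def test_seed_contract_bit_identical():
    d = _outcome_missing_data()
    ws = unit_weights(d, ALL)
    s1 = impute_regression(d, ws, SPEC_YX, 4, np.random.default_rng(99))
    s2 = impute_regression(d, ws, SPEC_YX, 4, np.random.default_rng(99))
    for a, b in zip(s1.values, s2.values):
        assert np.array_equal(a, b)


def test_imputation_mean_matches_least_squares_prediction():
    """Across many imputations the imputed values average to x'beta_hat."""
    d = _outcome_missing_data(n=10_000, frac=0.5, seed=8)
    ws = unit_weights(d, ALL)
    M = 200
    stack = impute_regression(d, ws, SPEC_YX, M, np.random.default_rng(5))
    mis = d.mask[:, 0]
    fit_rows = np.flatnonzero(~mis)
    X, y = build_design(d, SPEC_YX, rows=fit_rows)
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    sigma2 = resid @ resid / (len(y) - 2)
    Xm, _ = build_design(d, SPEC_YX, rows=np.flatnonzero(mis),
                         require_outcome=False)
    pred = Xm @ beta_hat
    imputed = np.stack([v[mis, 0] for v in stack.values])
    # Monte-Carlo SE of the mean over M proper draws, per missing row
    se = np.sqrt(sigma2 / M)
    frac_in = (np.abs(imputed.mean(axis=0) - pred) < 3 * se).mean()
    assert frac_in > 0.98


def test_sigma2_draws_follow_scaled_inverse_chisquare():
    """sigma^2* = RSS/chi2_{n-p}: distributional check on repeated draws."""
    rng = np.random.default_rng(17)
    n, p = 30, 2
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.array([1.0, 1.0]) + rng.standard_normal(n)
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta_hat) ** 2))
    draws = np.array([draw_regression_params(X, y, rng)[1] ** 2
                      for _ in range(2000)])
    # rss/sigma2* ~ chi2_{n-p}
    stat, pval = stats.kstest(rss / draws, stats.chi2(n - p).cdf)
    assert pval > 0.01


def test_degenerate_and_collinear_fits_raise(rng):
    d = _outcome_missing_data(n=3)
    ws = unit_weights(d, ALL)
    with pytest.raises(DegeneracyError):
        impute_regression(d, ws, ModelSpec("Y", ["X", ("X", "X")]), 2, rng)
    d2 = _outcome_missing_data(n=50)
    dup = from_frame(pd.DataFrame({
        "Y": d2.values[:, 0], "X": d2.values[:, 1], "X2": d2.values[:, 1]}))
    ws2 = unit_weights(dup, ALL)
    with pytest.raises(CollinearityError):
        impute_regression(dup, ws2, ModelSpec("Y", ["X", "X2"]), 2, rng)


# ---------------------------------------------------------------------------
# multivariate-normal block imputation
# ---------------------------------------------------------------------------

def _block_missing_data(n=2000, frac=0.5, seed=4, with_x5=True):
    rng = np.random.default_rng(seed)
    X2, X3, X4 = (rng.standard_normal(n) for _ in range(3))
    cols = {"X2": X2, "X3": X3, "X4": X4}
    if with_x5:
        cols["X5"] = X2 * X3 + rng.standard_normal(n)
    df = pd.DataFrame(cols)
    gone = rng.random(n) < frac
    df.loc[gone, :] = np.nan
    return from_frame(df)


def test_posterior_mean_concentrates_at_sample_mean(rng):
    d = _block_missing_data(n=20_000, frac=0.3, with_x5=False)
    ws = unit_weights(d, ALL)
    spec = MVNImputerSpec(block=("X2", "X3", "X4"))
    stack = impute_mvn_block(d, ws, spec, M=40, rng=rng)
    obs_rows = ~d.mask[:, 0]
    sample_mean = d.values[obs_rows].mean(axis=0)
    mus = np.stack([rec["mu"] for rec in stack.draws])
    n_obs = obs_rows.sum()
    se = np.sqrt(1.0 / n_obs) / np.sqrt(len(mus))  # posterior sd / sqrt(M)
    assert np.all(np.abs(mus.mean(axis=0) - sample_mean) < 4 * se)


def test_joint_normal_misspecification_erases_interaction():
    """A 4-variable joint normal cannot carry E[X5|X2,X3] = X2*X3: the fitted
    covariance is near-diagonal and imputed X5 is uncorrelated with X2*X3."""
    d = _block_missing_data(n=100_000, frac=0.5, seed=10)
    ws = unit_weights(d, ALL)
    spec = MVNImputerSpec(block=("X2", "X3", "X4", "X5"))
    stack = impute_mvn_block(d, ws, spec, M=1, rng=np.random.default_rng(1))
    Sigma = stack.draws[0]["Sigma"]
    off = Sigma - np.diag(np.diag(Sigma))
    assert np.max(np.abs(off)) < 0.05 * np.max(np.diag(Sigma))
    mis = d.mask[:, 0]
    vals = stack.values[0]
    r = np.corrcoef(vals[mis, 3], vals[mis, 0] * vals[mis, 1])[0, 1]
    assert abs(r) < 0.02


def test_conditional_regression_restores_interaction(rng):
    d = _block_missing_data(n=20_000, frac=0.5, seed=12)
    ws = unit_weights(d, ALL)
    spec = MVNImputerSpec(block=("X2", "X3", "X4"),
                          conditionals=(ModelSpec("X5", ["X2", "X3", ("X2", "X3")]),))
    stack = impute_mvn_block(d, ws, spec, M=1, rng=rng)
    mis = d.mask[:, 0]
    vals = stack.values[0]
    r = np.corrcoef(vals[mis, 3], vals[mis, 0] * vals[mis, 1])[0, 1]
    assert r > 0.5  # E[X5 | X2, X3] = X2*X3 is reproduced in the imputations


def test_block_fully_observed_gives_identical_copies(rng):
    d = _block_missing_data(n=200, frac=0.0)
    ws = unit_weights(d, ALL)
    stack = impute_mvn_block(d, ws, MVNImputerSpec(block=("X2", "X3", "X4")),
                             M=3, rng=rng)
    for vals in stack.values:
        assert np.allclose(vals, d.values)


def test_non_monotone_block_rejected(rng):
    df = pd.DataFrame({"X2": [1.0, np.nan, 2.0], "X3": [1.0, 1.0, np.nan]})
    d = from_frame(df)
    ws = unit_weights(d, ALL)
    with pytest.raises(ValidationError, match="monotone"):
        impute_mvn_block(d, ws, MVNImputerSpec(block=("X2", "X3")), 2, rng)


# ---------------------------------------------------------------------------
# weight terms in the imputation model
# ---------------------------------------------------------------------------

def test_attach_weight_terms_augments_and_is_idempotent():
    d = _outcome_missing_data()
    rule = ALL
    ws = set_known_weights(d, rule, np.full(d.n, 2.0))
    spec = ModelSpec("Y", ["X2", "X3"])
    aug = attach_weight_terms(spec, ws)
    assert aug.terms == (("X2",), ("X3",), ("W",), ("W", "X2"), ("W", "X3"))
    assert attach_weight_terms(aug, ws).terms == aug.terms


def test_constant_weights_make_augmented_design_collinear(rng):
    d = _outcome_missing_data(n=100)
    ws = set_known_weights(d, ALL, np.full(d.n, 2.0))
    aug = attach_weight_terms(ModelSpec("Y", ["X"]), ws)
    with pytest.raises(CollinearityError):
        impute_regression(d, ws, aug, 2, rng)
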