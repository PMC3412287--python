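"""Proper Bayesian multiple imputation.

Two imputation engines are provided, both *proper* (parameters are drawn
from their posterior before values are drawn from the predictive
distribution), fitted by unweighted maximum likelihood / conjugate Bayes on
the included individuals only.  Weights never enter as fitting weights; when
the theory requires them they enter the imputation model as covariates (see
:func:`attach_weight_terms`).

* Normal linear-regression imputation of an outcome, under the improper
  reference prior p(beta, sigma_eps) ∝ sigma_eps^{-2}: per imputation draw
  sigma^2* = RSS / chi^2_{n-p}, beta* ~ N(beta_hat, sigma^2* (X'X)^{-1}),
  then set each missing outcome to x'beta* + sigma* z with z standard
  normal.

* Multivariate-normal imputation of a jointly missing covariate block under
  the noninformative (Jeffreys-limit) normal–inverse-Wishart prior: per
  imputation draw Sigma* ~ InvWishart(n-1, S) and mu* ~ N(xbar, Sigma*/n),
  then draw each missing block from N(mu*, Sigma*).  Optional follow-on
  conditional regressions (e.g. a variable whose mean is a function of the
  block, interactions included) are imputed with the regression engine,
  using the freshly drawn block values as predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import IncompleteDataset, ModelSpec, build_design
from .errors import (
    CollinearityError,
    DegeneracyError,
    EstimationError,
    SpecificationError,
    ValidationError,
)
from .weights import WeightSet

WEIGHT_NAME = "W"
MAX_PD_RETRIES = 10


@dataclass(frozen=True)
class RegressionImputerSpec:
    """Normal linear-regression imputation model for one outcome."""

    model: ModelSpec

    @property
    def outcome(self) -> str:
        return self.model.outcome

    @property
    def has_weight_terms(self) -> bool:
        return any(WEIGHT_NAME in t for t in self.model.terms)


@dataclass(frozen=True)
class MVNImputerSpec:
    """Jointly normal covariate block plus optional conditional regressions."""

    block: tuple[str, ...]
    conditionals: tuple[ModelSpec, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "block", tuple(self.block))
        object.__setattr__(self, "conditionals", tuple(self.conditionals))
        for c in self.conditionals:
            unknown = {v for t in c.terms for v in t} - set(self.block)
            if unknown:
                raise SpecificationError(
                    f"conditional model for {c.outcome!r} uses variables {unknown} "
                    "outside the block"
                )


@dataclass
class ImputedStack:
    """M completed copies of the included individuals' data.

    ``values[m]`` is the full value matrix (rows = included individuals, in
    source row order; columns = dataset variables) of the m-th completed
    dataset.  Observed cells are identical across copies and equal to the
    source data; only cells that were missing differ.
    """

    values: list[np.ndarray]
    included: np.ndarray  # boolean over the source dataset's rows
    names: list[str]
    draws: list[dict] = field(default_factory=list)
    seed_record: object = None

    @property
    def M(self) -> int:
        return len(self.values)


def attach_weight_terms(spec: ModelSpec, weights: WeightSet) -> ModelSpec:
    """Augment an imputation model with W and the W x (term) interactions.

    Required when the analysis is weighted and the imputation model does not
    already carry the weight information through its own covariates: the
    imputer must not assume less structure across weight strata than the
    weighted analysis allows.  Idempotent.
    """
    if np.any(~np.isfinite(weights.weights)):
        raise ValidationError("weights must be available for all included rows")
    terms = list(spec.terms)
    new = []
    if spec.intercept and (WEIGHT_NAME,) not in terms:
        new.append((WEIGHT_NAME,))
    for t in terms:
        if WEIGHT_NAME in t:
            continue
        cand = (WEIGHT_NAME,) + t
        if cand not in terms and cand not in new:
            new.append(cand)
    if not new:
        return spec
    return ModelSpec(spec.outcome, terms + new, intercept=spec.intercept)


def _materialize_weight_column(
    data: IncompleteDataset, weights: WeightSet
) -> IncompleteDataset:
    w = np.where(weights.included, np.nan_to_num(weights.weights_all, nan=1.0), 1.0)
    return data.with_column(WEIGHT_NAME, w, roles=("auxiliary",))


def draw_regression_params(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One posterior draw (beta*, sigma*) under the reference prior."""
    n, p = X.shape
    if n <= p:
        raise DegeneracyError(
            f"imputation model needs more observed rows ({n}) than parameters ({p})"
        )
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= 1e-8 * s[0]:
        _, _, vt = np.linalg.svd(X)
        dep = np.flatnonzero(np.abs(vt[-1]) > 1e-6)
        raise CollinearityError(
            f"imputation design rank deficient; dependent columns {dep.tolist()}"
        )
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    sigma2 = rss / rng.chisquare(n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    L = np.linalg.cholesky(XtX_inv * sigma2)
    beta_star = beta_hat + L @ rng.standard_normal(p)
    return beta_star, float(np.sqrt(sigma2))


def impute_regression(
    data: IncompleteDataset,
    weights: WeightSet,
    spec: ModelSpec | RegressionImputerSpec,
    M: int,
    rng: np.random.Generator,
) -> ImputedStack:
    """Proper regression imputation of a missing outcome, M times.

    The model is fitted to included individuals with the outcome observed;
    predictors must be observed on every included row.  If the model
    references the weight variable ``W`` and the dataset has no such column,
    one is materialized from ``weights``.
    """
    if isinstance(spec, RegressionImputerSpec):
        spec = spec.model
    if M < 1:
        raise ValidationError("M must be >= 1")
    if any(WEIGHT_NAME in t for t in spec.terms) and WEIGHT_NAME not in data.names:
        data = _materialize_weight_column(data, weights)

    incl = weights.included
    incl_idx = np.flatnonzero(incl)
    obs_y = data.observed(spec.outcome)
    fit_rows = incl_idx[obs_y[incl_idx]]
    mis_rows = incl_idx[~obs_y[incl_idx]]

    X_fit, y_fit = build_design(data, spec, rows=fit_rows)
    if len(mis_rows):
        X_mis, _ = build_design(data, spec, rows=mis_rows, require_outcome=False)

    y_col = data.names.index(spec.outcome)
    base = data.values[incl_idx].copy()
    stack_vals: list[np.ndarray] = []
    draws: list[dict] = []
    mis_local = np.searchsorted(incl_idx, mis_rows)
    for _ in range(M):
        vals = base.copy()
        if len(mis_rows):
            beta_star, sigma_star = draw_regression_params(X_fit, y_fit, rng)
            vals[mis_local, y_col] = (
                X_mis @ beta_star + sigma_star * rng.standard_normal(len(mis_rows))
            )
            draws.append({"beta": beta_star, "sigma": sigma_star})
        else:
            draws.append({})
        stack_vals.append(vals)
    return ImputedStack(stack_vals, incl.copy(), list(data.names), draws)


def _niw_draw(
    Xb: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu*, Sigma*) from the Jeffreys-limit posterior given block rows."""
    n, d = Xb.shape
    if n <= d + 1:
        raise DegeneracyError(
            f"need more than {d + 1} complete block rows, got {n}"
        )
    xbar = Xb.mean(axis=0)
    S = (Xb - xbar).T @ (Xb - xbar)
    last_err = None
    for _ in range(MAX_PD_RETRIES):
        Sigma = stats.invwishart.rvs(df=n - 1, scale=S, random_state=rng)
        Sigma = np.atleast_2d(Sigma)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            last_err = exc
            continue
        mu = xbar + (L / np.sqrt(n)) @ rng.standard_normal(d)
        return mu, Sigma
    raise EstimationError(
        f"posterior covariance draw not positive definite after "
        f"{MAX_PD_RETRIES} retries: {last_err}"
    )  # pragma: no cover


def impute_mvn_block(
    data: IncompleteDataset,
    weights: WeightSet,
    spec: MVNImputerSpec,
    M: int,
    rng: np.random.Generator,
) -> ImputedStack:
    """Joint-normal imputation of a monotone missing covariate block, M times."""
    if M < 1:
        raise ValidationError("M must be >= 1")
    incl = weights.included
    incl_idx = np.flatnonzero(incl)
    block_cols = [data.names.index(v) for v in spec.block]
    bm = data.mask[np.ix_(incl_idx, block_cols)]
    partially = bm.any(axis=1) & ~bm.all(axis=1)
    if partially.any():
        raise ValidationError(
            "block is not monotone: some individuals have a partially "
            f"observed block (rows {incl_idx[partially][:10].tolist()})"
        )
    obs_local = np.flatnonzero(~bm.any(axis=1))
    mis_local = np.flatnonzero(bm.all(axis=1))

    cond_cols = [data.names.index(c.outcome) for c in spec.conditionals]
    # conditionals are fitted where the block AND the conditional outcome
    # are observed (among included individuals)
    base = data.values[incl_idx].copy()
    Xb_fit = base[np.ix_(obs_local, block_cols)]

    stack_vals: list[np.ndarray] = []
    draws: list[dict] = []
    for _ in range(M):
        vals = base.copy()
        rec: dict = {}
        if len(mis_local):
            mu, Sigma = _niw_draw(Xb_fit, rng)
            L = np.linalg.cholesky(Sigma)
            z = rng.standard_normal((len(mis_local), len(block_cols)))
            vals[np.ix_(mis_local, block_cols)] = mu + z @ L.T
            rec["mu"] = mu
            rec["Sigma"] = Sigma
        for cspec, ccol in zip(spec.conditionals, cond_cols):
            c_obs = ~data.mask[incl_idx, ccol]
            fit_local = obs_local[c_obs[obs_local]]
            need_local = np.flatnonzero(data.mask[incl_idx, ccol])
            X_fit, y_fit = build_design(
                data, cspec, rows=incl_idx[fit_local]
            )
            if len(need_local) == 0:
                continue
            beta_star, sigma_star = draw_regression_params(X_fit, y_fit, rng)
            # design for rows needing imputation, using drawn block values
            X_need = _design_from_values(vals, data.names, cspec, need_local)
            vals[need_local, ccol] = (
                X_need @ beta_star + sigma_star * rng.standard_normal(len(need_local))
            )
            rec[f"beta[{cspec.outcome}]"] = beta_star
            rec[f"sigma[{cspec.outcome}]"] = sigma_star
        stack_vals.append(vals)
        draws.append(rec)
    return ImputedStack(stack_vals, incl.copy(), list(data.names), draws)


def _design_from_values(
    vals: np.ndarray, names: list[str], spec: ModelSpec, rows: np.ndarray
) -> np.ndarray:
    cols = {v: vals[rows, names.index(v)] for t in spec.terms for v in t}
    ncol = len(spec.terms) + (1 if spec.intercept else 0)
    X = np.empty((len(rows), ncol))
    j = 0
    if spec.intercept:
        X[:, 0] = 1.0
        j = 1
    for t in spec.terms:
        prod = np.ones(len(rows))
        for v in t:
            prod = prod * cols[v]
        X[:, j] = prod
        j += 1
    return X
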