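"""The ST1/ST2 strategy engine.

Two stages of missingness are handled in order: stage 1 is missingness in a
covariate block, stage 2 is missingness in the analysis outcome among
individuals retained after stage 1.  At each stage the analyst may exclude
without adjustment (CC), exclude and inverse-probability weight (IPW), or
multiply impute (MI).  Supported pairs are CC/CC, CC/IPW, CC/MI, IPW/CC,
IPW/IPW, IPW/MI and MI/MI; MI/CC and MI/IPW are rejected — they combine the
burden of specifying a block imputation model with the efficiency loss of
discarding outcome information.

Each completed (quasi-complete) dataset is analysed by weighted least
squares (or weighted logistic regression) with the sandwich variance, and
the per-imputation fits are combined by Rubin's rules.  Strategies without
imputation return a single-fit pooled result (M = 1, between-variance 0)
for interface uniformity.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    IncompleteDataset,
    InclusionRule,
    ModelSpec,
    build_design,
)
from .errors import StrategyError, ValidationError
from .estimators import QuasiCompleteFit, weighted_logistic_fit, wls_fit
from .imputation import (
    MVNImputerSpec,
    RegressionImputerSpec,
    WEIGHT_NAME,
    draw_regression_params,
    impute_mvn_block,
    impute_regression,
    _design_from_values,
)
from .pooling import PooledFit, pool, single_fit_pooled
from .weights import (
    WeightModelSpec,
    WeightSet,
    fit_missingness_model,
    product_weights,
    unit_weights,
)

SUPPORTED_PAIRS = {
    ("CC", "CC"), ("CC", "IPW"), ("CC", "MI"),
    ("IPW", "CC"), ("IPW", "IPW"), ("IPW", "MI"),
    ("MI", "MI"),
}


@dataclass(frozen=True)
class StrategySpec:
    """One ST1/ST2 strategy: stage choices plus the models each stage needs."""

    stage1: str
    stage2: str
    stage1_block: tuple[str, ...]
    imputer1: MVNImputerSpec | None = None
    imputer2: ModelSpec | RegressionImputerSpec | None = None
    weight_model1: WeightModelSpec | None = None
    weight_model2: WeightModelSpec | None = None
    M: int = 10
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "stage1_block", tuple(self.stage1_block))
        if (self.stage1, self.stage2) not in SUPPORTED_PAIRS:
            raise StrategyError(
                f"unsupported strategy {self.stage1}/{self.stage2}; supported: "
                + ", ".join(sorted(f"{a}/{b}" for a, b in SUPPORTED_PAIRS))
            )
        if not self.label:
            object.__setattr__(self, "label", f"{self.stage1}/{self.stage2}")
        if self.stage1 == "IPW" and self.weight_model1 is None:
            raise StrategyError("stage-1 IPW needs weight_model1")
        if self.stage2 == "IPW" and self.weight_model2 is None:
            raise StrategyError("stage-2 IPW needs weight_model2")
        if self.stage1 == "MI" and self.imputer1 is None:
            raise StrategyError("stage-1 MI needs imputer1")
        if self.stage2 == "MI" and self.imputer2 is None:
            raise StrategyError("stage-2 MI needs imputer2")
        if ("MI" in (self.stage1, self.stage2)) and self.M < 2:
            raise StrategyError("imputation strategies need M >= 2")

    @property
    def uses_imputation(self) -> bool:
        return "MI" in (self.stage1, self.stage2)


def strategy_rng(seed: int, label: str, replicate: int | None = None):
    """Stable per-strategy RNG substream derived from a master seed.

    The substream key hashes the strategy label, so adding or reordering
    strategies never perturbs another strategy's draws.
    """
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    parts = (seed, key) if replicate is None else (seed, replicate, key)
    return np.random.default_rng(np.random.SeedSequence(parts))


def _imputer2_model(spec: StrategySpec) -> ModelSpec:
    imp = spec.imputer2
    return imp.model if isinstance(imp, RegressionImputerSpec) else imp


def _analysis_fit(
    X: np.ndarray, y: np.ndarray, W: np.ndarray, family: str, labels
) -> QuasiCompleteFit:
    if family == "logistic":
        return weighted_logistic_fit(y, X, W, labels=labels)
    return wls_fit(y, X, W, labels=labels)


def run_strategy(
    data: IncompleteDataset,
    spec: StrategySpec,
    analysis: ModelSpec,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    family: str = "linear",
) -> PooledFit:
    """Apply one ST1/ST2 strategy to a dataset and return the pooled fit."""
    if set(spec.stage1_block) & {analysis.outcome}:
        raise StrategyError("stage-1 block must not contain the analysis outcome")
    if rng is None:
        rng = strategy_rng(0 if seed is None else seed, spec.label)
    outcome = analysis.outcome
    labels = analysis.column_labels
    block_rule = InclusionRule.block_complete(spec.stage1_block)

    # ---- stage 1 ---------------------------------------------------------
    if spec.stage1 == "MI":
        ws1 = unit_weights(data, InclusionRule.all_rows())
        stack1 = impute_mvn_block(data, ws1, spec.imputer1, spec.M, rng)
    else:
        stack1 = None
        if spec.stage1 == "CC":
            ws1 = unit_weights(data, block_rule)
        else:  # IPW
            ws1 = fit_missingness_model(data, block_rule, spec.weight_model1)
        if ws1.n_included == 0:
            raise ValidationError("no individuals included after stage 1")

    # ---- stage 2 ---------------------------------------------------------
    if spec.stage1 == "MI":
        # stage 2 is MI by construction: impute the outcome within each
        # block-completed copy, then fit unweighted on all rows
        fits = []
        imp2 = _imputer2_model(spec)
        y_col = data.names.index(outcome)
        y_obs = data.observed(outcome)
        y_mis = np.flatnonzero(~y_obs)
        fit_rows = np.flatnonzero(y_obs)
        for m in range(spec.M):
            vals = stack1.values[m]
            Xf = _design_from_values(vals, data.names, imp2, fit_rows)
            yf = vals[fit_rows, y_col]
            if len(y_mis):
                beta_star, sigma_star = draw_regression_params(Xf, yf, rng)
                Xm = _design_from_values(vals, data.names, imp2, y_mis)
                vals = vals.copy()
                vals[y_mis, y_col] = (
                    Xm @ beta_star + sigma_star * rng.standard_normal(len(y_mis))
                )
            Xa = _design_from_values(vals, data.names, analysis,
                                     np.arange(data.n))
            fits.append(_analysis_fit(Xa, vals[:, y_col], np.ones(data.n),
                                      family, labels))
        return pool(fits)

    incl1 = ws1.included
    y_observed = data.observed(outcome)

    if spec.stage2 == "MI":
        imp2 = spec.imputer2
        if isinstance(imp2, RegressionImputerSpec):
            imp2 = imp2.model
        stack2 = impute_regression(data, ws1, imp2, spec.M, rng)
        W = ws1.weights
        rows = np.flatnonzero(incl1)
        y_col = data.names.index(outcome)
        fits = []
        for m in range(spec.M):
            vals = stack2.values[m]
            Xa = _design_from_values(vals, data.names, analysis,
                                     np.arange(len(rows)))
            fits.append(_analysis_fit(Xa, vals[:, y_col], W, family, labels))
        return pool(fits)

    # stage 2 is CC or IPW: exclude rows with missing outcome
    final_incl = incl1 & y_observed
    if not final_incl.any():
        raise ValidationError("no complete cases remain after stage 2")
    if spec.stage2 == "IPW":
        # stage-2 weight predictors must be fully observed among the rows
        # retained after stage 1; tag them in the subset (re-validates)
        data1 = data.subset(incl1).adding_role(
            "weight_predictor", spec.weight_model2.variables
        )
        rule_y = InclusionRule(required=(outcome,), name="outcome_observed")
        ws2_local = fit_missingness_model(data1, rule_y, spec.weight_model2)
        pi2 = np.ones(data.n)
        pi2[incl1] = ws2_local.pi_all
        incl2 = np.zeros(data.n, dtype=bool)
        incl2[np.flatnonzero(incl1)[ws2_local.included]] = True
        ws2 = WeightSet(incl2, pi2, alpha=ws2_local.alpha,
                        known_weights=False, link=spec.weight_model2.link)
        ws_final = product_weights(ws1, ws2)
    else:
        pi2 = np.ones(data.n)
        ws2 = WeightSet(final_incl, pi2, known_weights=True, link="unit")
        ws_final = product_weights(ws1, ws2)

    X, y = build_design(data, analysis, rows=ws_final.included)
    fit = _analysis_fit(X, y, ws_final.weights, family, labels)
    return single_fit_pooled(fit)


def validate_conditions(spec: StrategySpec, data: IncompleteDataset) -> list[str]:
    """Advisory checks on the compatibility of weighting and imputation.

    Consistency of a weighted analysis after imputation requires the
    imputation model to carry the weight information: it must include the
    weight W (or the estimated weight), or all the weight-model predictors
    Z.  For a linear outcome imputed under a weighted analysis, unbiased
    Rubin's-rules variances additionally want the W x (analysis covariate)
    interactions unless the imputer's own covariates subsume them.  Returns
    a list of warning strings (also emitted via ``warnings.warn``); never
    raises.
    """
    report: list[str] = []
    if spec.stage1 == "IPW" and spec.stage2 == "MI":
        imp = _imputer2_model(spec)
        imp_vars = {v for t in imp.terms for v in t}
        zvars = set(spec.weight_model1.variables) if spec.weight_model1 else set()
        has_w = WEIGHT_NAME in imp_vars
        covers_z = bool(zvars) and zvars <= imp_vars
        if not (has_w or covers_z):
            report.append(
                "stage-2 imputation model contains neither the weight W nor "
                "all stage-1 weight-model predictors; imputations fitted to "
                "the weighted-in subsample may be biased (include W, the "
                "estimated weight, or Z in the imputation model)"
            )
            report.append(
                "weight-by-covariate interaction terms (W x analysis "
                "covariates) are absent from the outcome imputation model; "
                "Rubin's-rules variance may be biased for the weighted "
                "analysis (use attach_weight_terms)"
            )
    for msg in report:
        warnings.warn(msg, UserWarning, stacklevel=2)
    return report
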