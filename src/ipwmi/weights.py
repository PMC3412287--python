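"""Missingness (weighting) models and inverse-probability weights.

The inclusion indicator g(R) partitions the sample; a model pi(Z; alpha) for
P(g(R)=1 | Z) is fitted by maximum likelihood to ALL individuals, and each
included individual receives weight W = 1/pi_hat.  Two links are supported:

* ``logistic`` — logistic regression of the inclusion indicator on Z (with
  intercept);
* ``saturated`` — one probability per cell of the full cross-classification
  of (discrete) Z; the MLE is the within-cell inclusion proportion.  This is
  the identity-link binomial fit without its boundary problems, and is exact
  for a missingness probability linear in a single binary predictor.

Positivity: the theory requires inclusion probabilities bounded away from
zero.  A fitted pi below the floor ``delta`` raises a PositivityError rather
than truncating (truncation changes the estimand); truncation is available
behind ``truncate=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import IncompleteDataset, InclusionRule, Term, _as_terms
from .errors import CompositionError, PositivityError, ValidationError

DEFAULT_FLOOR = 1e-6


@dataclass(frozen=True)
class WeightModelSpec:
    """Missingness-model specification: fully observed predictors + link.

    ``predictors`` are terms: a bare name is a main effect, a tuple of names
    a rowwise product (e.g. ``("X2", "X4")`` for a model in X2*X4).
    """

    predictors: tuple[Term, ...]
    link: str = "logistic"  # "logistic" | "saturated"

    def __post_init__(self):
        if self.link not in ("logistic", "saturated"):
            raise ValidationError(f"unknown link {self.link!r}")
        object.__setattr__(self, "predictors", _as_terms(self.predictors))

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.predictors:
            for v in t:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)


@dataclass
class WeightSet:
    """Inclusion indicator, fitted probabilities, and weights W = 1/pi.

    ``pi_all`` holds the fitted probability for every individual in the
    source dataset; weights are defined (and meaningful) only where
    ``included`` is True.  ``score_design`` retains the logistic design used
    to fit alpha, enabling the weight-adjusted sandwich.
    """

    included: np.ndarray
    pi_all: np.ndarray
    alpha: np.ndarray | None = None
    known_weights: bool = False
    floor: float = DEFAULT_FLOOR
    score_design: np.ndarray | None = None
    link: str | None = None

    def __post_init__(self):
        self.included = np.asarray(self.included, dtype=bool)
        self.pi_all = np.asarray(self.pi_all, dtype=float)
        pi_inc = self.pi_all[self.included]
        if np.any(~np.isfinite(pi_inc)) or np.any(pi_inc <= 0) or np.any(pi_inc > 1):
            raise ValidationError("inclusion probabilities must lie in (0, 1]")
        if np.any(pi_inc < self.floor):
            raise PositivityError(
                f"fitted inclusion probability below positivity floor {self.floor:g}"
            )

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def weights(self) -> np.ndarray:
        """W_i = 1/pi_i for included individuals (in row order)."""
        return 1.0 / self.pi_all[self.included]

    @property
    def weights_all(self) -> np.ndarray:
        """Full-length weight vector, NaN for excluded individuals."""
        w = np.full(self.pi_all.shape, np.nan)
        w[self.included] = 1.0 / self.pi_all[self.included]
        return w


def unit_weights(data: IncompleteDataset, rule: InclusionRule) -> WeightSet:
    """All included individuals weighted 1 (unweighted complete-case analysis)."""
    incl = rule.included(data)
    return WeightSet(incl, np.ones(data.n), known_weights=True, link="unit")


def _stratum_design(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot design over the full cross-classification of discrete Z."""
    cells, codes = np.unique(Z, axis=0, return_inverse=True)
    D = np.zeros((Z.shape[0], len(cells)))
    D[np.arange(Z.shape[0]), codes] = 1.0
    return D, codes


def fit_missingness_model(
    data: IncompleteDataset,
    rule: InclusionRule,
    spec: WeightModelSpec,
    floor: float = DEFAULT_FLOOR,
    truncate: bool = False,
) -> WeightSet:
    """ML fit of the inclusion indicator on Z over all N individuals."""
    for v in spec.variables:
        if v not in data.names:
            raise ValidationError(f"weight predictor {v!r} not in dataset")
        if "weight_predictor" not in data.roles[v]:
            raise ValidationError(
                f"variable {v!r} lacks the weight_predictor role"
            )
    g = rule.included(data).astype(float)
    if not g.any():
        raise ValidationError("no individuals satisfy the inclusion rule")
    if g.all():
        # degenerate but well-defined: everyone included with probability 1
        return WeightSet(g.astype(bool), np.ones(data.n), alpha=None,
                         known_weights=False, floor=floor, link=spec.link)
    cols = []
    for t in spec.predictors:
        prod = np.ones(data.n)
        for v in t:
            prod = prod * data.column(v)
        cols.append(prod)
    Z = np.column_stack(cols)

    if spec.link == "saturated":
        D, codes = _stratum_design(Z)
        counts = D.sum(axis=0)
        incl_counts = D.T @ g
        if np.any(incl_counts == 0):
            empty = np.flatnonzero(incl_counts == 0).tolist()
            raise PositivityError(
                f"strata {empty} contain no included individuals"
            )
        p_cell = incl_counts / counts
        pi = p_cell[codes]
        with np.errstate(divide="ignore"):
            alpha = np.log(p_cell) - np.log1p(-p_cell)  # logit scale; inf if p=1
        design = D
    else:
        from .estimators import weighted_logistic_fit

        design = np.column_stack([np.ones(data.n), Z])
        fit = weighted_logistic_fit(g, design)
        alpha = fit.theta
        from scipy.special import expit

        pi = expit(design @ alpha)

    if truncate:
        pi = np.maximum(pi, floor)
    incl = g.astype(bool)
    if np.any(pi[incl] < floor):
        raise PositivityError(
            f"fitted inclusion probability below floor {floor:g}; "
            "inspect the weight model or enable truncation explicitly"
        )
    return WeightSet(incl, pi, alpha=alpha, known_weights=False, floor=floor,
                     score_design=design, link=spec.link)


def set_known_weights(
    data: IncompleteDataset,
    rule: InclusionRule,
    weights: np.ndarray,
) -> WeightSet:
    """Wrap externally supplied (known) weights for the included individuals.

    ``weights`` may be full length (entries at excluded positions ignored)
    or one entry per included individual in row order.
    """
    incl = rule.included(data)
    weights = np.asarray(weights, dtype=float)
    w_inc = weights[incl] if weights.shape == (data.n,) else weights
    if w_inc.shape != (int(incl.sum()),):
        raise ValidationError("need one weight per included individual")
    if np.any(~np.isfinite(w_inc)) or np.any(w_inc <= 0):
        raise ValidationError("known weights must be positive and finite")
    if np.any(w_inc < 1):
        raise ValidationError("inclusion weights must be >= 1 (pi = 1/W <= 1)")
    pi = np.ones(data.n)
    pi[incl] = 1.0 / w_inc
    return WeightSet(incl, pi, known_weights=True, link="known")


def product_weights(stage1: WeightSet, stage2: WeightSet) -> WeightSet:
    """Compose two exclusion stages: pi = pi1 * pi2 on the stage-2 set."""
    if stage1.included.shape != stage2.included.shape:
        raise CompositionError("weight sets cover different samples")
    if np.any(stage2.included & ~stage1.included):
        raise CompositionError(
            "stage-2 inclusion set is not a subset of stage-1 inclusion set"
        )
    pi = stage1.pi_all * stage2.pi_all
    return WeightSet(
        stage2.included.copy(), pi,
        known_weights=stage1.known_weights and stage2.known_weights,
        floor=min(stage1.floor, stage2.floor),
        link="product",
    )
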