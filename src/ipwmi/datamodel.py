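"""Core data containers: incomplete datasets, inclusion rules, model specs.

An :class:`IncompleteDataset` is a rectangular individuals x variables table
of real values together with an explicit boolean missingness mask (the mask,
not a sentinel value, is authoritative).  Variables carry *roles* —
``outcome``, ``covariate`` (analysis covariate), ``auxiliary``,
``weight_predictor`` — which may overlap.  Weight predictors must be fully
observed, because inclusion probabilities are modelled on them for every
individual, included or not.

Variables are continuous or {0,1}-coded binary; categorical expansion is the
caller's responsibility.  Row order is the identity key; an optional id
column is carried through but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IncompleteDataError,
    RoleViolationError,
    SpecificationError,
    ValidationError,
)

ROLES = ("outcome", "covariate", "auxiliary", "weight_predictor")

# A term is a tuple of variable names; ("X2",) is a main effect,
# ("X2", "X3") the rowwise product X2*X3.
Term = tuple[str, ...]


def _as_terms(terms: Iterable) -> tuple[Term, ...]:
    out = []
    for t in terms:
        if isinstance(t, str):
            out.append((t,))
        else:
            out.append(tuple(t))
    return tuple(out)


def term_label(term: Term) -> str:
    return ":".join(term)


@dataclass(frozen=True)
class ModelSpec:
    """Analysis (or imputation) model: outcome, terms, intercept flag."""

    outcome: str
    terms: tuple[Term, ...]
    intercept: bool = True

    def __init__(self, outcome: str, terms: Iterable, intercept: bool = True):
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "terms", _as_terms(terms))
        object.__setattr__(self, "intercept", bool(intercept))
        seen = set()
        for t in self.terms:
            key = tuple(sorted(t))
            if key in seen:
                raise SpecificationError(f"duplicate term {term_label(t)!r}")
            seen.add(key)

    @property
    def variables(self) -> set[str]:
        return {v for t in self.terms for v in t} | {self.outcome}

    @property
    def column_labels(self) -> list[str]:
        cols = ["Intercept"] if self.intercept else []
        return cols + [term_label(t) for t in self.terms]


@dataclass(frozen=True)
class InclusionRule:
    """Deterministic predicate over missingness patterns R.

    ``required`` names the variable block that must be fully observed for an
    individual to be included (the default two-stage rule: included iff the
    stage-1 block is complete).  Custom predicates receive the boolean
    missingness row in dataset variable order.
    """

    required: tuple[str, ...] = ()
    predicate: Callable[[np.ndarray], bool] | None = None
    name: str = "block_complete"

    @staticmethod
    def block_complete(variables: Sequence[str]) -> "InclusionRule":
        return InclusionRule(required=tuple(variables))

    @staticmethod
    def all_rows() -> "InclusionRule":
        return InclusionRule(required=(), name="all")

    def included(self, data: "IncompleteDataset") -> np.ndarray:
        """Boolean inclusion indicator g(R_i) for every individual."""
        if self.predicate is not None:
            return np.array([bool(self.predicate(row)) for row in data.mask])
        if not self.required:
            return np.ones(data.n, dtype=bool)
        idx = [data.names.index(v) for v in self.required]
        return ~data.mask[:, idx].any(axis=1)


@dataclass
class IncompleteDataset:
    """Individuals x variables table with explicit missingness mask and roles."""

    values: np.ndarray
    mask: np.ndarray
    names: list[str]
    roles: dict[str, frozenset[str]]
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if self.values.shape[1] != len(self.names):
            raise ValidationError("column count does not match variable names")
        for v, rr in self.roles.items():
            if v not in self.names:
                raise SpecificationError(f"role assigned to unknown variable {v!r}")
            bad = set(rr) - set(ROLES)
            if bad:
                raise SpecificationError(f"unknown roles {bad} for variable {v!r}")
        self.roles = {v: frozenset(r) for v, r in self.roles.items()}
        for v in self.names:
            self.roles.setdefault(v, frozenset())
        # weight predictors must be fully observed for everyone
        for v in self.with_role("weight_predictor"):
            if self.mask[:, self.names.index(v)].any():
                raise RoleViolationError(
                    f"weight predictor {v!r} has missing values; weight predictors "
                    "must be fully observed"
                )
        # hide masked entries behind NaN so accidental use is loud
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    # -- basic views ------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def pattern(self) -> np.ndarray:
        """Per-individual missingness pattern R_i (True = missing)."""
        return self.mask

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def observed(self, name: str) -> np.ndarray:
        """Boolean indicator that `name` is observed per individual."""
        return ~self.mask[:, self.names.index(name)]

    def with_role(self, role: str) -> list[str]:
        return [v for v in self.names if role in self.roles[v]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        return df

    def subset(self, rows: np.ndarray) -> "IncompleteDataset":
        ids = self.ids[rows] if self.ids is not None else None
        return IncompleteDataset(
            self.values[rows], self.mask[rows], list(self.names),
            dict(self.roles), ids,
        )

    def adding_role(self, role: str, variables: Iterable[str]) -> "IncompleteDataset":
        """Copy with `role` added to the named variables (invariants re-checked)."""
        new_roles = dict(self.roles)
        for v in variables:
            if v not in self.names:
                raise SpecificationError(f"unknown variable {v!r}")
            new_roles[v] = new_roles[v] | {role}
        return IncompleteDataset(self.values, self.mask, list(self.names),
                                 new_roles, self.ids)

    def with_column(
        self, name: str, values: np.ndarray, roles: Iterable[str] = ()
    ) -> "IncompleteDataset":
        """Return a copy with an extra fully observed column appended."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n,):
            raise ValidationError(f"column {name!r} has wrong length")
        if name in self.names:
            raise SpecificationError(f"variable {name!r} already exists")
        new_vals = np.column_stack([self.values, values])
        new_mask = np.column_stack([self.mask, np.zeros(self.n, dtype=bool)])
        new_roles = dict(self.roles)
        new_roles[name] = frozenset(roles)
        return IncompleteDataset(new_vals, new_mask, self.names + [name],
                                 new_roles, self.ids)


def from_frame(
    df: pd.DataFrame,
    roles: dict[str, Iterable[str]] | None = None,
    id_column: str | None = None,
) -> IncompleteDataset:
    """Build an :class:`IncompleteDataset` from a DataFrame (NaN = missing)."""
    ids = None
    if id_column is not None and id_column in df.columns:
        ids = df[id_column].to_numpy()
        df = df.drop(columns=[id_column])
    values = df.to_numpy(dtype=float)
    mask = np.isnan(values)
    roles = {v: frozenset(r) for v, r in (roles or {}).items()}
    return IncompleteDataset(values, mask, list(df.columns), roles, ids)


def read_dataset(
    path,
    missing_code: str = "NA",
    roles: dict[str, Iterable[str]] | None = None,
    id_column: str | None = None,
) -> IncompleteDataset:
    """Read a header-row CSV, flagging ``missing_code`` (and empty cells).

    Non-numeric, non-missing cells raise a parse error naming the row and
    column.  A weight-predictor column containing the missing code raises a
    role-violation error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = [c for c in df.columns if c != id_column]
    values = np.empty((len(df), len(names)))
    mask = np.zeros_like(values, dtype=bool)
    for j, c in enumerate(names):
        col = df[c].to_numpy()
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell == missing_code or cell == "":
                mask[i, j] = True
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"cannot parse cell {cell!r} at row {i}, column {c!r}"
                    ) from None
    roles = {v: frozenset(r) for v, r in (roles or {}).items()}
    ids = df[id_column].to_numpy() if id_column and id_column in df.columns else None
    return IncompleteDataset(values, mask, names, roles, ids)


def write_dataset(data: IncompleteDataset, path, missing_code: str = "NA") -> None:
    """Write a dataset to CSV; masked cells become ``missing_code``."""
    df = data.to_frame()
    df.to_csv(path, index=False, na_rep=missing_code)


def build_design(
    data: IncompleteDataset,
    spec: ModelSpec,
    rows: np.ndarray | None = None,
    values: np.ndarray | None = None,
    require_outcome: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and outcome vector for `spec` on the requested rows.

    Columns are ordered intercept first, then terms in spec order; product
    terms are computed rowwise.  `values` optionally overrides the dataset's
    value matrix (same shape) so completed (imputed) copies can reuse the
    spec; the mask of the original dataset is ignored in that case.

    Raises :class:`IncompleteDataError` if any requested row has a missing
    term variable, listing the offending rows.
    """
    for v in spec.variables:
        if v not in data.names:
            raise SpecificationError(f"model references unknown variable {v!r}")
    if rows is None:
        rows = np.arange(data.n)
    rows = np.asarray(rows)
    if rows.dtype == bool:
        rows = np.flatnonzero(rows)
    vals = data.values if values is None else np.asarray(values, dtype=float)
    col = {v: vals[rows, data.names.index(v)] for v in spec.variables}

    needed = sorted({v for t in spec.terms for v in t})
    if require_outcome:
        needed = sorted(set(needed) | {spec.outcome})
    if values is None and len(rows):
        miss = np.zeros(len(rows), dtype=bool)
        for v in needed:
            miss |= data.mask[rows, data.names.index(v)]
        if miss.any():
            bad = rows[miss][:20]
            raise IncompleteDataError(
                f"rows {bad.tolist()} have missing values for model variables"
            )

    ncol = len(spec.terms) + (1 if spec.intercept else 0)
    X = np.empty((len(rows), ncol))
    j = 0
    if spec.intercept:
        X[:, 0] = 1.0
        j = 1
    for t in spec.terms:
        prod = np.ones(len(rows))
        for v in t:
            prod = prod * col[v]
        X[:, j] = prod
        j += 1
    y = col[spec.outcome] if spec.outcome in col else vals[rows, data.names.index(spec.outcome)]
    return X, y
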