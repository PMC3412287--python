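"""Exception hierarchy.

Validation errors (bad inputs, contract violations) derive from
:class:`ValidationError`; numerical/estimation failures derive from
:class:`EstimationError`.  The CLI maps the former to exit code 2 and the
latter to exit code 1.
"""


class IpwmiError(Exception):
    """Base class for all package errors."""


class ValidationError(IpwmiError, ValueError):
    """Input violates a documented precondition or invariant."""


class SpecificationError(ValidationError):
    """A model specification references unknown variables or duplicates terms."""


class RoleViolationError(ValidationError):
    """A variable is used in a role its observed data cannot support."""


class IncompleteDataError(ValidationError):
    """Rows requested for a design matrix have missing term variables."""


class PositivityError(ValidationError):
    """A fitted inclusion probability is zero or below the positivity floor."""


class CompositionError(ValidationError):
    """Two weight sets cannot be composed (stage-2 set not nested in stage-1)."""


class StrategyError(ValidationError):
    """Unsupported or inconsistent stage-1/stage-2 strategy combination."""


class PoolingError(ValidationError):
    """Fewer than two fits supplied to Rubin's-rules pooling."""


class EstimationError(IpwmiError, RuntimeError):
    """Numerical failure: non-convergence, separation, rank deficiency."""


class CollinearityError(EstimationError):
    """Design matrix is rank deficient."""


class DegeneracyError(EstimationError):
    """Too few observed rows to fit an imputation or analysis model."""
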