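"""Exception hierarchy.

All package errors derive from :class:`InductionScopeError` so callers can
catch broadly; subclasses map to the distinct failure modes of the module
contracts (format vs. validation vs. degenerate numerics).
"""


class InductionScopeError(Exception):
    """Base class for all package-specific errors."""


class PlateFormatError(InductionScopeError):
    """A required column or structural element of an input file is missing."""


class PlateValidationError(InductionScopeError):
    """The file parses but its content violates a dataset invariant."""


class DegenerateCurveError(InductionScopeError):
    """A signal is constant (zero variance) where variation is required."""


class GridCoverageError(InductionScopeError):
    """A culture's time range does not cover the requested common grid."""


class InsufficientDataError(InductionScopeError):
    """Fewer observations than the operation's stated minimum."""


class MissingReferenceError(InductionScopeError):
    """No kept fit of a non-induced reference well is available."""


class DegenerateReferenceError(InductionScopeError):
    """Reference features are non-positive and cannot serve as denominators."""


class CollinearityError(InductionScopeError):
    """The regression design matrix is rank deficient."""


class RegimeConfigError(InductionScopeError):
    """A simulation regime requests an unrealizable parameter combination."""
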