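"""Exception hierarchy.

Validation-type failures (bad configuration, malformed input files, schema
mismatches) derive from :class:`ValidationError`; numeric failures in an
otherwise well-posed computation derive from :class:`NumericError`.  The CLI
maps these to exit codes 2 and 3 respectively.
"""


class TopoconnError(Exception):
    """Base class for all package errors."""


class ValidationError(TopoconnError):
    """Invalid configuration, parameters, or input data schema."""


class InvalidConfigError(ValidationError):
    """A simulation or run configuration violates its invariants."""


class InvalidParameterError(ValidationError):
    """An operation parameter is outside its documented domain."""


class InsufficientDataError(ValidationError):
    """Too few observations/samples for the requested computation."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate (e.g. a constant node row)."""


class NumericError(TopoconnError):
    """A well-formed computation has no defined answer on this input."""


class DegenerateScaleError(NumericError):
    """A standardization scale (baseline SD) is zero."""


class UndefinedSegregationError(NumericError):
    """Mean within-network connectivity is non-positive; normalization collapses."""


class UndefinedModularityError(NumericError):
    """Modularity is undefined (no positive edge weight)."""


class DegenerateCurveError(NumericError):
    """A Betti curve has too few points to integrate."""


class DegenerateMediatorError(NumericError):
    """The mediator has zero variance; paths a and b are undefined."""


class CollinearityError(NumericError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)
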