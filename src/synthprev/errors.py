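"""Exception hierarchy.

All package errors derive from :class:`SynthprevError` so callers can catch
one base class; the subclasses distinguish configuration mistakes, schema
mismatches, degenerate estimation inputs and model-fitting failures.
"""


class SynthprevError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynthprevError):
    """A configuration object or file is invalid."""


class SchemaError(SynthprevError):
    """A dataset is missing a column/term required by a model or operation."""


class EstimationError(SynthprevError):
    """An estimator received degenerate input (empty area, zero total weight)."""


class SpecificationError(SynthprevError):
    """A model specification is unusable (duplicate terms, <2 groups, ...)."""


class DesignMatrixError(SynthprevError):
    """The fixed-effect design matrix is rank deficient."""

    def __init__(self, message: str, collinear_terms=None):
        super().__init__(message)
        self.collinear_terms = list(collinear_terms or [])


class FitError(SynthprevError):
    """Model fitting failed (separation or non-convergence).

    Carries iteration diagnostics when available.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SeparationError(FitError):
    """The likelihood is maximized at infinity (perfect separation)."""


class UndefinedMetricError(SynthprevError):
    """A performance metric is undefined for this input (single-class outcome,
    constant risks)."""
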