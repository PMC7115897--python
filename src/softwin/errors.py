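"""Exception hierarchy.

Everything derives from :class:`SoftwinError` so callers can catch the
package's failures with one clause; each class also subclasses ValueError
because the conditions are, without exception, bad input values.
"""


class SoftwinError(Exception):
    """Base class for all softwin errors."""


class InvalidParameterError(SoftwinError, ValueError):
    """A window parameter is outside its domain (e.g. nonpositive shape)."""


class EmptyInputError(SoftwinError, ValueError):
    """An operation received an empty time/observation vector."""


class DegenerateCurveError(SoftwinError, ValueError):
    """A peak curve cannot be normalized (maximum not strictly positive)."""


class ShapeMismatchError(SoftwinError, ValueError):
    """Vectors that must be aligned have different lengths."""


class SingularDesignError(SoftwinError, ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, collinear, message=None):
        self.collinear = list(collinear)
        super().__init__(
            message or f"design matrix is rank deficient; collinear terms: {self.collinear}"
        )


class MissingGroupError(SoftwinError, ValueError):
    """A required group level (control or mutant) is absent."""


class InsufficientDataError(SoftwinError, ValueError):
    """Too few observations for the requested statistical operation."""


class InfeasibleSlideError(SoftwinError, ValueError):
    """The mutant time structure does not fit inside the control time span."""


class SchemaError(SoftwinError, ValueError):
    """An input table is missing mandatory columns."""

    def __init__(self, missing, message=None):
        self.missing = list(missing)
        super().__init__(message or f"input table is missing mandatory columns: {self.missing}")


class ConfigError(SoftwinError, ValueError):
    """A simulation or run configuration is internally inconsistent."""
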