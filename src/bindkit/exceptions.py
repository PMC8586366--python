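"""Exception hierarchy.

All errors raised by the package derive from :class:`BindkitError`, with
:class:`ValidationError` covering malformed input data and
:class:`ParameterError` covering nonphysical parameter values.
"""


class BindkitError(Exception):
    """Base class for all bindkit errors."""


class ValidationError(BindkitError, ValueError):
    """Input data violates a documented invariant."""


class MissingColumnError(ValidationError):
    """A required column is absent from a delimited input table."""


class NonNumericCellError(ValidationError):
    """A cell that must be numeric could not be parsed."""


class DuplicateConcentrationError(ValidationError):
    """A titration series contains the same quencher concentration twice."""


class MissingZeroConcentrationError(ValidationError):
    """A titration series lacks the mandatory zero-concentration (F0) row."""


class ParameterError(BindkitError, ValueError):
    """A supplied parameter value is outside its physical domain."""


class InsufficientDataError(BindkitError, ValueError):
    """Too few eligible data points to perform the requested analysis."""


class InsufficientEvidenceError(BindkitError, ValueError):
    """Fewer than two evidence sources supplied to the binding-mode combiner."""


class DegenerateSolventError(BindkitError, ValueError):
    """DNA flow time does not exceed the buffer flow time."""


class ZeroHardnessError(BindkitError, ValueError):
    """HOMO and LUMO are degenerate: softness and electrophilicity undefined."""


class BoundaryPeakError(BindkitError, ValueError):
    """A spectral maximum falls on the edge of the scanned wavelength range."""
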