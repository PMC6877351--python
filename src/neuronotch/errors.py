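"""Exception hierarchy for neuronotch.

All package-specific failures derive from :class:`NeuronotchError` so callers
can catch one base class. Validation errors are raised eagerly at spec
construction or operation entry, never deferred to silent NaN propagation.
"""


class NeuronotchError(Exception):
    """Base class for all neuronotch errors."""


class InvalidSpecificationError(NeuronotchError, ValueError):
    """A stage/signal specification violates its invariants."""


class InvalidArgumentError(NeuronotchError, ValueError):
    """An operation argument is outside its admissible domain."""


class InvalidRateError(NeuronotchError, ValueError):
    """A sample rate is unusable (too low, or a non-integer resample ratio)."""


class OutOfBandError(NeuronotchError, ValueError):
    """A requested frequency is at or above the Nyquist rate of a digital model."""


class IncompatibleTraceError(NeuronotchError, ValueError):
    """Two traces (or a trace and a channel) disagree in rate or length."""


class InvalidTraceError(NeuronotchError, ValueError):
    """A trace violates its own invariants (empty, non-finite samples)."""


class TraceParseError(NeuronotchError, ValueError):
    """A trace CSV file could not be parsed.

    Carries the 1-based line number at which parsing failed (``None`` when
    the failure is not attributable to a single line, e.g. a missing header).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UndefinedNormalizationError(NeuronotchError, ZeroDivisionError):
    """A normalization constant is zero (e.g. constant RMSE reference)."""


class ResolutionError(NeuronotchError, ValueError):
    """A spectral measurement cannot resolve the requested frequency."""


class InsufficientLevelError(NeuronotchError, ValueError):
    """Distortion products are below the measurable spectral floor."""


class DesignFailureError(NeuronotchError, RuntimeError):
    """A filter design template could not be met."""


class DesignCaveatWarning(UserWarning):
    """A design succeeds but with a documented behavioural caveat."""
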