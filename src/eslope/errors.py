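"""Exception hierarchy for eslope.

All validation failures raise a subclass of :class:`EslopeError`, so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class EslopeError(Exception):
    """Base class for all eslope errors."""


class InvalidInputError(EslopeError, ValueError):
    """An argument violates an operation's precondition."""


class StateError(EslopeError):
    """An operation was applied to an object in the wrong state
    (e.g. shifting a curve whose depths were already EPOM-shifted)."""


class LevelNotFoundError(EslopeError, LookupError):
    """A requested ionization level is never crossed on the descending limb."""


class InsufficientDataError(EslopeError):
    """Too few samples fall inside a fitting window."""


class DegenerateFitError(EslopeError):
    """A line fit is degenerate (parallel lines, intersection on the wrong
    side of the fitting window, ...)."""


class ScanFormatError(EslopeError, ValueError):
    """A scan or log file is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigurationError(EslopeError):
    """A tool configuration is incomplete or inconsistent."""
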