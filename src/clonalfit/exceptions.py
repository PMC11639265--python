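"""Exception hierarchy shared across the package."""


class ClonalFitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ClonalFitError, ValueError):
    """Raised when data passed to a computation violates its preconditions."""


class ShapeError(InvalidInputError):
    """Raised on dimension mismatches between parameters and data."""


class ConfigurationError(ClonalFitError, ValueError):
    """Raised when optimizer or search configuration is inconsistent."""


class UndefinedMetricError(InvalidInputError):
    """Raised when a metric is undefined for the given input (e.g. single-class AUC)."""


class ParseError(ClonalFitError, ValueError):
    """Raised when a dataset file cannot be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class GenerationError(ClonalFitError, RuntimeError):
    """Raised when a synthetic-data spec cannot produce a valid dataset."""
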