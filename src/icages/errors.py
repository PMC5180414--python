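"""Exception hierarchy shared across the package."""


class IcagesError(Exception):
    """Base class for all package errors."""


class ParseError(IcagesError):
    """Malformed input file content (carries a line number when known)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(IcagesError):
    """Input file contained no usable records."""


class ConfigurationError(IcagesError):
    """Invalid or incomplete run configuration."""


class SampleLookupError(IcagesError):
    """Requested sample not present in the VCF."""


class InvalidIntervalError(IcagesError):
    """Interval with start >= end (BED) or start > end (queries)."""


class SortOrderError(IcagesError):
    """Database rows are not sorted by key then coordinate."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DataError(IcagesError):
    """Out-of-range or inconsistent data values."""


class TrainingError(IcagesError):
    """Model training cannot proceed (single class, bad folds, ...)."""


class CollinearityError(TrainingError):
    """A feature pair exceeds the collinearity threshold."""


class ConvergenceError(TrainingError):
    """Optimizer failed to converge; for separable data carries the
    diverging weight direction."""

    def __init__(self, message: str, direction=None):
        super().__init__(message)
        self.direction = direction


class NotFittedError(IcagesError):
    """Model used before being fitted or loaded."""
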