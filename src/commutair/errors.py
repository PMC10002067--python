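"""Exception hierarchy shared across the package."""


class CommutairError(Exception):
    """Base class for all package errors."""


class FormatError(CommutairError, ValueError):
    """A file does not conform to the expected schema (e.g. missing column)."""


class RowParseError(CommutairError, ValueError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ConfigError(CommutairError, ValueError):
    """Configuration value violates an invariant (negative rate, bad ratio...)."""


class ParameterError(CommutairError, ValueError):
    """A function argument is outside its physical or mathematical domain."""


class FitError(CommutairError, ValueError):
    """A regression cannot be fitted (too few points, unpaired dates...)."""


class SingularityError(FitError):
    """A regressor has zero variance, or a fitted equation is non-invertible."""


class InsufficientDataError(CommutairError, ValueError):
    """Not enough usable data survives filtering (e.g. < 3 humidogram bins)."""


class NoPathError(CommutairError, ValueError):
    """The destination is unreachable from the origin in the route graph."""
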