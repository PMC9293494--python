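"""Exception hierarchy shared across the pipeline."""


class HerbNetPharmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HerbNetPharmError):
    """A configuration value, column mapping, or format choice is invalid."""


class ParseError(HerbNetPharmError):
    """An input file could not be parsed; carries the offending location."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ValidationError(HerbNetPharmError):
    """A domain invariant was violated."""


class ConvergenceWarning(UserWarning):
    """An iterative numerical routine stopped before reaching tolerance."""
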