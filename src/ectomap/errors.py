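"""Exception hierarchy shared by all ectomap modules."""


class EctomapError(Exception):
    """Base class for all ectomap errors."""


class InvalidParameterError(EctomapError, ValueError):
    """A configuration or function parameter is outside its allowed range."""


class InvalidInputError(EctomapError, ValueError):
    """Input data are structurally unusable (missing wells, empty table, ...)."""


class ParseError(EctomapError, ValueError):
    """A text file could not be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ReferenceMismatchError(EctomapError, ValueError):
    """Coordinates or chromosome names do not fit the genome definition."""


class UndefinedStatisticError(EctomapError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
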