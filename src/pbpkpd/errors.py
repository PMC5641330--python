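"""Exception hierarchy for the pbpkpd package.

Every user-facing error derives from :class:`PbpkError` so callers (and the
CLI) can catch one base class and exit non-zero.
"""


class PbpkError(Exception):
    """Base class for all pbpkpd errors."""


class ConfigError(PbpkError):
    """A configuration file is malformed, has unknown keys, or missing fields."""


class RangeError(PbpkError):
    """A parameter value violates its physical/physiological range."""


class SpeciesLookupError(PbpkError, KeyError):
    """Requested species (or tissue) is not in the shipped physiology tables."""


class ParseError(PbpkError):
    """A delimited data file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DomainError(PbpkError):
    """An input is outside the mathematical domain of an operation."""


class PreconditionError(PbpkError):
    """A documented precondition of an operation is not met."""


class SolverError(PbpkError):
    """ODE integration failed; carries the last good state for diagnosis."""

    def __init__(self, message: str, t_last: float | None = None, y_last=None):
        self.t_last = t_last
        self.y_last = y_last
        super().__init__(message)
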