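"""Exception hierarchy for annotation parsing and analysis."""


class SongDataError(ValueError):
    """Base class for all domain errors raised by this package."""


class FormatError(SongDataError):
    """A required column or structural element is missing from an input file."""


class ParseError(SongDataError):
    """A field could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SongDataError):
    """Parsed values violate a domain invariant (time order, label grammar...)."""


class DomainError(SongDataError):
    """An operation was called outside its mathematical domain (empty set...)."""


class AnalysisError(SongDataError):
    """A pipeline stage cannot run on the assembled inputs."""


class ConsistencyError(SongDataError):
    """Two structures that must agree (tree nodes vs. support table) do not."""
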