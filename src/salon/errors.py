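"""Exception hierarchy for the salon package."""


class SalonError(Exception):
    """Base class for all package-specific errors."""


class RaggedAlignmentError(SalonError):
    """Sequences within one sub-alignment have unequal aligned lengths."""


class MixedGapError(SalonError):
    """Both '-' and '.' occur as gap symbols in the same alignment block."""


class EmptyColumnError(SalonError):
    """An operation received an empty alignment column."""


class AllGapColumnError(SalonError):
    """Entropy is undefined on a column that contains only gap characters."""


class MacsimParseError(SalonError):
    """MACSIM XML could not be parsed; carries a line number when available."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FastaFormatError(SalonError):
    """Input text is not valid FASTA."""


class FastaDialectError(SalonError):
    """A description line does not follow the requested header dialect."""


class UnsupportedFormatError(SalonError):
    """Unknown RDF serialization label."""


class SchemaViolationError(SalonError):
    """A model/graph assertion violates the registered schema.

    ``violations`` holds the individual findings when more than one was
    collected before raising.
    """

    def __init__(self, message: str, violations: list | None = None):
        self.violations = violations or []
        super().__init__(message)


class MissingScoreError(SalonError):
    """A column lacks the score required by a reliability measure."""


class ScoreRangeError(SalonError):
    """A reliability score falls outside the measure's declared range."""
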