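"""Exception hierarchy shared across the pipeline."""


class ChromaprimeError(Exception):
    """Base class for all package errors."""


class MalformedRecord(ChromaprimeError):
    """A file record violates the format or a coordinate invariant.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DuplicateKey(ChromaprimeError):
    """A key required to be unique (gene_id, sample label) occurs twice."""


class UnwritablePath(ChromaprimeError):
    """Output path cannot be created or written."""


class ConfigError(ChromaprimeError):
    """Invalid configuration (simulation or pipeline)."""


class StageError(ChromaprimeError):
    """A pipeline stage failed; the stage name is included in the message."""


class DegenerateSample(ChromaprimeError):
    """A sample has a zero scaling statistic (median or depth)."""


class MissingFactor(ChromaprimeError):
    """A sample in the matrix has no normalization factor."""


class WindowSetMismatch(ChromaprimeError):
    """Two call sets are defined on different window sets."""


class InsufficientWindows(ChromaprimeError):
    """Fewer eligible windows than requested."""


class LengthMismatch(ChromaprimeError):
    """Boolean flag vectors over the same query differ in length."""


class MissingSequence(ChromaprimeError):
    """Genome sequence unavailable for a requested region."""


class EmptyMatrix(ChromaprimeError):
    """Operation requires at least one row."""
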