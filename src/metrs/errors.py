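"""Exception types shared across the toolkit."""


class MetrsError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MetrsError, ValueError):
    """A text input (taxonomy TSV/FASTA, hits TSV, SAM, ...) is malformed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnknownEntryError(MetrsError, KeyError):
    """A hit references a database entry id that the reference DB lacks."""

    def __init__(self, read_id: str, entry_id: str):
        super().__init__(
            f"read {read_id!r} hits entry {entry_id!r} absent from the reference DB"
        )
        self.read_id = read_id
        self.entry_id = entry_id


class ContractViolation(MetrsError, ValueError):
    """A documented precondition was violated by the caller."""
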