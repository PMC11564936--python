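"""Exception hierarchy shared across the package."""


class PhenocurateError(Exception):
    """Base class for all package errors."""


class FormatError(PhenocurateError):
    """Malformed input file or document structure."""


class StructuralError(PhenocurateError):
    """Graph-level inconsistency, e.g. a cycle in the is_a hierarchy."""


class LookupError_(PhenocurateError):
    """Reference to a term or entity that is not present."""


class ValidationError(PhenocurateError):
    """A domain-type invariant was violated at construction time."""


class ParseError(PhenocurateError):
    """A scalar value (age, CURIE, cell) could not be interpreted."""


class ArgumentError(PhenocurateError):
    """A function argument violates its contract."""


class CellError(PhenocurateError):
    """A curation-table cell could not be interpreted; carries coordinates."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = ""
        if self.row is not None or self.column is not None:
            loc = f" (row={self.row}, column={self.column})"
        return super().__str__() + loc


class EmptyCorpusError(PhenocurateError):
    """A corpus directory yielded zero readable phenopackets."""
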