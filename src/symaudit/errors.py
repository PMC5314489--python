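"""Exception hierarchy for symaudit."""


class SymauditError(Exception):
    """Base class for all symaudit errors."""


class MissingColumnError(SymauditError):
    """A mapped column is absent from a table header."""


class DuplicateIdError(SymauditError):
    """A gene id or primary accession occurs more than once in a table."""


class MalformedRecordError(SymauditError):
    """A row violates a record invariant (empty id, bad entry name, ...)."""


class MalformedAccessionError(SymauditError):
    """An identifier does not satisfy the accession lexical rules.

    Distinct from an accession that is well-formed but absent from the
    loaded protein table (which resolves to status ``unknown``).
    """


class EmptyIndexError(SymauditError):
    """An operation requiring a non-empty table or symbol index got none."""


class MitabParseError(SymauditError):
    """A PSI-MITAB line could not be parsed in strict mode."""


class InfeasibleSpecError(SymauditError):
    """A synthetic-table redundancy spec cannot be satisfied."""


class CurationError(SymauditError):
    """The curated reference is unusable (e.g. unresolvable query protein)."""
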