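"""Resolution of symbols, accessions and entry names to unambiguous records.

Every query resolves to exactly one of four statuses:

* ``unambiguous``      — exactly one target record/gene
* ``ambiguous``        — two or more candidate genes share the symbol
* ``unknown``          — nothing in the loaded tables carries the identifier
* ``secondary_redirect`` — a superseded accession, redirected to the
  current primary

Accessions are validated lexically before lookup: a malformed accession is
an error (the caller passed something that cannot be an accession), while a
well-formed accession absent from the table is merely ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING

from ._accession import is_valid_accession
from .errors import MalformedAccessionError
from .symtable import ProteinTable

if TYPE_CHECKING:  # pragma: no cover
    from .redundancy import SymbolIndex


class Status(Enum):
    UNAMBIGUOUS = "unambiguous"
    AMBIGUOUS = "ambiguous"
    UNKNOWN = "unknown"
    SECONDARY_REDIRECT = "secondary_redirect"


@dataclass
class Resolution:
    """Outcome of resolving one identifier.

    Invariants: unambiguous <=> 1 target; ambiguous <=> >=2 targets;
    unknown <=> 0 targets; secondary_redirect carries exactly one target
    (the current primary) and names the superseded accession in ``note``.
    """

    query: str
    status: Status
    targets: tuple = ()
    note: str = ""

    def __post_init__(self) -> None:
        n = len(self.targets)
        expected = {
            Status.UNAMBIGUOUS: n == 1,
            Status.AMBIGUOUS: n >= 2,
            Status.UNKNOWN: n == 0,
            Status.SECONDARY_REDIRECT: n == 1,
        }
        if not expected[self.status]:
            raise ValueError(
                f"{self.status.value} resolution with {n} targets"
            )


def validate_accession(candidate: str, extended: bool = False) -> bool:
    """True iff *candidate* is lexically a valid protein accession.

    The default contract is the classic form: exactly six consecutive
    alphanumeric characters, first character alphabetic, uppercase, no
    spaces or special characters. ``extended=True`` additionally accepts
    the ten-character form used for newer accessions (off by default).
    """
    return is_valid_accession(candidate, extended=extended)


def resolve_symbol(index: "SymbolIndex", symbol: str) -> Resolution:
    """Resolve a gene symbol through the redundancy index.

    Pure trichotomy over the symbol's degree: 0 -> unknown,
    1 -> unambiguous, >=2 -> ambiguous (all candidate gene ids listed).
    """
    genes = index.genes_for(symbol)
    if len(genes) == 0:
        return Resolution(query=symbol, status=Status.UNKNOWN)
    if len(genes) == 1:
        return Resolution(
            query=symbol, status=Status.UNAMBIGUOUS, targets=genes
        )
    return Resolution(
        query=symbol,
        status=Status.AMBIGUOUS,
        targets=genes,
        note=f"symbol shared by {len(genes)} genes",
    )


def resolve_accession(
    table: ProteinTable, accession: str, extended: bool = False
) -> Resolution:
    """Resolve a protein accession against the loaded protein table.

    A primary hit is unambiguous; a hit among some record's secondary
    accessions redirects to that record's primary (the table guarantees a
    unique owner); no hit is unknown. A lexically malformed accession
    raises :class:`MalformedAccessionError` instead of resolving.
    """
    if not validate_accession(accession, extended=extended):
        raise MalformedAccessionError(
            f"{accession!r} is not a valid accession (expected six "
            f"consecutive alphanumeric characters, first alphabetic)"
        )
    if table.by_primary(accession) is not None:
        return Resolution(
            query=accession, status=Status.UNAMBIGUOUS, targets=(accession,)
        )
    primary = table.primary_for_secondary(accession)
    if primary is not None:
        return Resolution(
            query=accession,
            status=Status.SECONDARY_REDIRECT,
            targets=(primary,),
            note=f"secondary accession {accession} superseded by {primary}",
        )
    return Resolution(query=accession, status=Status.UNKNOWN)


def resolve_entry_name(table: ProteinTable, entry_name: str) -> Resolution:
    """Resolve an entry name (MNEMONIC_SPECIES) by exact match.

    Entry names are human-readable but may change between database
    releases, so this is an interpretation layer: exact match only, and
    the note flags the lower stability of this identifier class.
    """
    rec = table.by_entry_name(entry_name)
    if rec is None:
        return Resolution(query=entry_name, status=Status.UNKNOWN)
    return Resolution(
        query=entry_name,
        status=Status.UNAMBIGUOUS,
        targets=(rec.primary_accession,),
        note="matched via entry name (entry names may change between releases)",
    )


def detect_identifier_type(identifier: str) -> str:
    """Classify an identifier string: accession, entry_name, or symbol."""
    text = identifier.strip()
    if is_valid_accession(text, extended=True):
        return "accession"
    parts = text.split("_")
    if len(parts) == 2 and all(parts):
        return "entry_name"
    return "symbol"


def resolve_any(
    index: "SymbolIndex",
    proteins: ProteinTable,
    identifier: str,
    extended: bool = False,
) -> tuple:
    """Detect an identifier's type and resolve it with the matching rule.

    Returns ``(detected_type, Resolution)``. Used by the ``resolve`` CLI
    over mixed identifier lists.
    """
    kind = detect_identifier_type(identifier)
    if kind == "accession":
        return kind, resolve_accession(proteins, identifier.strip(),
                                       extended=extended)
    if kind == "entry_name":
        return kind, resolve_entry_name(proteins, identifier.strip())
    return kind, resolve_symbol(index, identifier.strip())
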