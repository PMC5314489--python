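"""Interaction auditing: PSI-MITAB I/O, ambiguity flagging, multi-source
merging and curation against a literature-derived evidence table.

The workflow mirrors how interaction evidence is actually assembled:

1. retrieve interaction lists from several databases (MITAB exports),
2. flag participants named by ambiguous symbols or outdated accessions,
3. merge the lists on a canonical interaction identity, and
4. classify each merged interaction against a manually curated reference
   (supported by published experiments, rejected as a known false
   positive, or unverified).

MITAB dialect: the minimal 15-column PSI-MITAB 2.5 layout. Only columns
1-2 (interactor ids), 7 (detection method), 9 (publication id) and 13
(source database) are consumed; all columns pass through round trips
verbatim.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from ._accession import is_valid_accession
from .errors import CurationError, MalformedRecordError, MitabParseError
from .redundancy import SymbolIndex
from .symtable import ProteinRecord, ProteinTable

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MITAB_COLUMNS = 15
_COL_ID_A, _COL_ID_B = 0, 1
_COL_METHOD, _COL_PUBLICATION, _COL_SOURCE_DB = 6, 8, 12

#: Namespaces treated as gene-symbol identifiers.
SYMBOL_NAMESPACES = frozenset({"genesymbol", "gene symbol", "hgnc", "symbol"})
#: Namespaces treated as protein accessions.
ACCESSION_NAMESPACES = frozenset({"uniprotkb", "uniprot", "swiss-prot", "sp"})
#: Full declared vocabulary; anything else is preserved verbatim and tagged.
KNOWN_NAMESPACES = (
    SYMBOL_NAMESPACES
    | ACCESSION_NAMESPACES
    | frozenset(
        {"entrez gene/locuslink", "intact", "string", "psi-mi", "pubmed",
         "taxid", "chebi", "refseq", "ensembl", "gene"}
    )
)


@dataclass(frozen=True)
class Identifier:
    """A namespaced participant identifier, e.g. uniprotkb:P35790."""

    namespace: str
    value: str

    @property
    def known(self) -> bool:
        return self.namespace in KNOWN_NAMESPACES

    @property
    def is_symbol(self) -> bool:
        return self.namespace in SYMBOL_NAMESPACES

    @property
    def is_accession(self) -> bool:
        return self.namespace in ACCESSION_NAMESPACES

    def __str__(self) -> str:
        if self.namespace:
            return f"{self.namespace}:{self.value}"
        return self.value

    @classmethod
    def parse(cls, raw: str) -> "Identifier":
        text = raw.strip()
        if ":" in text:
            ns, value = text.split(":", 1)
            return cls(namespace=ns.strip().lower(), value=value.strip())
        return cls(namespace="", value=text)


@dataclass
class InteractionRecord:
    """One MITAB row: two namespaced participants plus provenance."""

    id_a: Identifier
    id_b: Identifier
    source_db: str = ""
    detection_method: str = ""
    publication: str = ""
    raw_line_no: int = 1
    columns: tuple = ()  # full original row for pass-through writes

    def __post_init__(self) -> None:
        if not self.id_a.value or not self.id_b.value:
            raise MalformedRecordError(
                f"line {self.raw_line_no}: both participant identifiers "
                f"must be non-empty"
            )
        if self.raw_line_no < 1:
            raise MalformedRecordError("raw_line_no must be >= 1")


class FlagType(Enum):
    AMBIGUOUS_SYMBOL = "AMBIGUOUS_SYMBOL"
    UNKNOWN_SYMBOL = "UNKNOWN_SYMBOL"
    SECONDARY_ACCESSION = "SECONDARY_ACCESSION"
    MALFORMED_ACCESSION = "MALFORMED_ACCESSION"


@dataclass
class AuditFlag:
    """One problem found on one participant of one interaction record."""

    record: InteractionRecord
    participant: str  # "A" or "B"
    flag: FlagType
    detail: str = ""

    COLUMNS = ("line", "participant", "identifier", "flag", "detail")

    def as_row(self) -> dict:
        ident = self.record.id_a if self.participant == "A" else self.record.id_b
        return {
            "line": self.record.raw_line_no,
            "participant": self.participant,
            "identifier": str(ident),
            "flag": self.flag.value,
            "detail": self.detail,
        }


# ---------------------------------------------------------------------------
# MITAB I/O


def read_mitab(
    path: PathLike, strict: bool = True, min_columns: int = 2
) -> List[InteractionRecord]:
    """Parse a PSI-MITAB file into interaction records.

    Comment lines (``#``) and blank lines are skipped. In strict mode an
    unparseable line raises :class:`MitabParseError` with its line number;
    in lenient mode it is skipped with a log message.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            cols = stripped.split("\t")
            try:
                if len(cols) < min_columns:
                    raise MitabParseError(
                        f"{path}:{lineno}: {len(cols)} columns, expected "
                        f">= {min_columns}"
                    )
                record = InteractionRecord(
                    id_a=Identifier.parse(cols[_COL_ID_A]),
                    id_b=Identifier.parse(cols[_COL_ID_B]),
                    detection_method=_col(cols, _COL_METHOD),
                    publication=_col(cols, _COL_PUBLICATION),
                    source_db=_col(cols, _COL_SOURCE_DB),
                    raw_line_no=lineno,
                    columns=tuple(cols),
                )
            except (MitabParseError, MalformedRecordError) as exc:
                if strict:
                    if isinstance(exc, MitabParseError):
                        raise
                    raise MitabParseError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("skipping unparseable MITAB line %s:%d (%s)",
                               path, lineno, exc)
                continue
            records.append(record)
    return records


def _col(cols: Sequence[str], idx: int) -> str:
    if idx < len(cols) and cols[idx] != "-":
        return cols[idx]
    return ""


def write_mitab(records: Iterable[InteractionRecord], path: PathLike) -> None:
    """Write records as 15-column MITAB, preserving pass-through columns."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if rec.columns:
                cols = list(rec.columns)
            else:
                cols = ["-"] * MITAB_COLUMNS
            while len(cols) < MITAB_COLUMNS:
                cols.append("-")
            cols[_COL_ID_A] = str(rec.id_a)
            cols[_COL_ID_B] = str(rec.id_b)
            if rec.detection_method:
                cols[_COL_METHOD] = rec.detection_method
            if rec.publication:
                cols[_COL_PUBLICATION] = rec.publication
            if rec.source_db:
                cols[_COL_SOURCE_DB] = rec.source_db
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# auditing


def audit_interactions(
    records: Iterable[InteractionRecord],
    index: SymbolIndex,
    proteins: ProteinTable,
    extended_accessions: bool = False,
) -> List[AuditFlag]:
    """Flag participants attributed via ambiguous symbols or stale accessions.

    Auditing is total: every record is examined, clean participants
    produce no flag, and no input ever raises. Symbol-namespace
    participants get redundancy-degree checks; accession-namespace
    participants get lexical validation and secondary-redirect checks.
    Other namespaces are out of audit scope and pass through unflagged.
    """
    flags = []
    for record in records:
        for side, ident in (("A", record.id_a), ("B", record.id_b)):
            flag = _audit_participant(
                record, side, ident, index, proteins, extended_accessions
            )
            if flag is not None:
                flags.append(flag)
    return flags


def _audit_participant(
    record: InteractionRecord,
    side: str,
    ident: Identifier,
    index: SymbolIndex,
    proteins: ProteinTable,
    extended: bool,
) -> Optional[AuditFlag]:
    if ident.is_symbol:
        genes = index.genes_for(ident.value)
        if len(genes) >= 2:
            return AuditFlag(
                record=record,
                participant=side,
                flag=FlagType.AMBIGUOUS_SYMBOL,
                detail=(
                    f"degree={len(genes)}; candidate genes: "
                    + ",".join(genes)
                ),
            )
        if len(genes) == 0:
            return AuditFlag(
                record=record,
                participant=side,
                flag=FlagType.UNKNOWN_SYMBOL,
                detail="no gene in the loaded table carries this symbol",
            )
        return None
    if ident.is_accession:
        if not is_valid_accession(ident.value, extended=extended):
            return AuditFlag(
                record=record,
                participant=side,
                flag=FlagType.MALFORMED_ACCESSION,
                detail=f"{ident.value!r} fails accession validation",
            )
        primary = proteins.primary_for_secondary(ident.value)
        if primary is not None:
            return AuditFlag(
                record=record,
                participant=side,
                flag=FlagType.SECONDARY_ACCESSION,
                detail=f"superseded secondary accession → {primary}",
            )
        return None
    return None


# ---------------------------------------------------------------------------
# merging


@dataclass
class MergedInteraction:
    """One canonical interaction after multi-source merging.

    ``id_a``/``id_b`` are the canonical participants (unordered pair,
    stored sorted); ``provenance`` lists contributing (source_db,
    publication) pairs; ``members`` keeps the original records.
    ``fully_resolved`` is False when at least one participant could not be
    promoted to a primary accession or unique gene — such records only
    merge within their own source database.
    """

    id_a: Identifier
    id_b: Identifier
    provenance: tuple
    members: tuple
    fully_resolved: bool

    COLUMNS = ("id_a", "id_b", "n_sources", "provenance", "fully_resolved")

    def as_row(self) -> dict:
        return {
            "id_a": str(self.id_a),
            "id_b": str(self.id_b),
            "n_sources": len(self.provenance),
            "provenance": "|".join(
                f"{db or '-'}:{pub or '-'}" for db, pub in self.provenance
            ),
            "fully_resolved": self.fully_resolved,
        }


def _canonical_participant(
    ident: Identifier,
    index: Optional[SymbolIndex],
    proteins: Optional[ProteinTable],
) -> tuple:
    """Canonical form of one participant: (Identifier, resolved flag).

    Accessions map to their current primary; symbols of degree exactly 1
    are promoted to the corresponding protein's primary accession (or a
    gene-namespace id when no protein record links to the gene). Ambiguous
    or unknown symbols, malformed accessions and unknown namespaces stay
    verbatim and are marked unresolved — merging on those is precisely the
    error class this toolkit exists to catch.
    """
    if ident.is_accession:
        if not is_valid_accession(ident.value, extended=True):
            return ident, False
        if proteins is not None:
            primary = proteins.primary_for_secondary(ident.value)
            if primary is not None:
                return Identifier("uniprotkb", primary), True
        return Identifier("uniprotkb", ident.value), True
    if ident.is_symbol:
        if index is None:
            return ident, False
        genes = index.genes_for(ident.value)
        if len(genes) != 1:
            return ident, False
        gene_id = genes[0]
        if proteins is not None:
            rec = proteins.by_gene_id(gene_id)
            if rec is not None:
                return Identifier("uniprotkb", rec.primary_accession), True
        return Identifier("gene", gene_id), True
    if ident.known:
        return ident, True
    return ident, False


def merge_sources(
    lists: Sequence[Sequence],
    index: Optional[SymbolIndex] = None,
    proteins: Optional[ProteinTable] = None,
) -> List[MergedInteraction]:
    """Merge interaction lists from multiple sources.

    Records whose canonical unordered participant pairs are equal collapse
    into one merged interaction with concatenated provenance. Records with
    an unresolved participant never merge across source databases. Output
    order is deterministic: sorted by canonical pair. Merging is
    idempotent (already-merged input passes through unchanged) and
    commutative over input list order.
    """
    if not lists:
        raise ValueError("merge_sources requires at least one input list")
    groups: dict = {}
    order_keys = []
    for source in lists:
        for item in source:
            if isinstance(item, MergedInteraction):
                pair = (item.id_a, item.id_b)
                resolved = item.fully_resolved
                provenance = list(item.provenance)
                members = list(item.members)
                source_db = item.members[0].source_db if item.members else ""
            else:
                ca, ra = _canonical_participant(item.id_a, index, proteins)
                cb, rb = _canonical_participant(item.id_b, index, proteins)
                pair = tuple(sorted((ca, cb), key=str))
                resolved = ra and rb
                provenance = [(item.source_db, item.publication)]
                members = [item]
                source_db = item.source_db
            key = (str(pair[0]), str(pair[1]))
            if not resolved:
                key = key + (source_db,)
            if key not in groups:
                groups[key] = {
                    "pair": pair,
                    "resolved": resolved,
                    "provenance": [],
                    "members": [],
                }
                order_keys.append(key)
            bucket = groups[key]
            for prov in provenance:
                if prov not in bucket["provenance"]:
                    bucket["provenance"].append(prov)
            bucket["members"].extend(members)
    merged = []
    for key in sorted(order_keys):
        bucket = groups[key]
        merged.append(
            MergedInteraction(
                id_a=bucket["pair"][0],
                id_b=bucket["pair"][1],
                provenance=tuple(bucket["provenance"]),
                members=tuple(bucket["members"]),
                fully_resolved=bucket["resolved"],
            )
        )
    return merged


# ---------------------------------------------------------------------------
# curation


class EntryStatus(Enum):
    SUPPORTED = "supported"
    REJECTED = "rejected"


@dataclass
class CuratedEntry:
    """One literature-curated evidence row for a partner protein.

    Rejected entries document known false positives (e.g. partners listed
    only because of a shared abbreviation) and must carry a rationale in
    ``notes``. ``partner_accession`` may be empty only for symbol-only
    rejected entries whose accession was never part of the flagged listing.
    """

    partner_symbol: str
    partner_accession: str = ""
    partner_entry: str = ""
    year: int = 1900
    reference: str = ""
    experimental_model: str = ""
    detection_method: str = ""
    notes: str = ""
    status: EntryStatus = EntryStatus.SUPPORTED

    def __post_init__(self) -> None:
        if isinstance(self.status, str):
            self.status = EntryStatus(self.status)
        if not self.partner_symbol:
            raise MalformedRecordError("curated entry needs a partner symbol")
        if self.partner_accession and not is_valid_accession(
            self.partner_accession, extended=True
        ):
            raise MalformedRecordError(
                f"curated entry {self.partner_symbol}: invalid accession "
                f"{self.partner_accession!r}"
            )
        if not self.partner_accession and self.status is EntryStatus.SUPPORTED:
            raise MalformedRecordError(
                f"supported entry {self.partner_symbol} must cite an accession"
            )
        self.year = int(self.year)
        if self.year < 1900:
            raise MalformedRecordError(
                f"curated entry {self.partner_symbol}: implausible year "
                f"{self.year}"
            )
        if self.status is EntryStatus.REJECTED and not self.notes.strip():
            raise MalformedRecordError(
                f"rejected entry {self.partner_symbol} requires a rationale "
                f"in notes"
            )


@dataclass
class CuratedInteractome:
    """A query protein plus its manually curated evidence rows."""

    query_protein: ProteinRecord
    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for entry in self.entries:
            key = entry.partner_accession or f"symbol:{entry.partner_symbol}"
            if key in seen:
                raise MalformedRecordError(
                    f"duplicate curated partner {key!r}"
                )
            seen.add(key)
            if not entry.reference.strip():
                raise MalformedRecordError(
                    f"curated entry {entry.partner_symbol} cites no reference"
                )

    def by_accession(self, accession: str) -> Optional[CuratedEntry]:
        for entry in self.entries:
            if entry.partner_accession and entry.partner_accession == accession:
                return entry
        return None

    def by_symbol(self, symbol: str) -> Optional[CuratedEntry]:
        for entry in self.entries:
            if entry.partner_symbol == symbol:
                return entry
        return None

    def supported(self) -> List[CuratedEntry]:
        return [e for e in self.entries if e.status is EntryStatus.SUPPORTED]

    def rejected(self) -> List[CuratedEntry]:
        return [e for e in self.entries if e.status is EntryStatus.REJECTED]


CURATED_COLUMNS = (
    "partner_symbol",
    "partner_accession",
    "partner_entry",
    "year",
    "reference",
    "experimental_model",
    "detection_method",
    "notes",
    "status",
)


def read_curated_table(
    path: PathLike, query_protein: ProteinRecord
) -> CuratedInteractome:
    """Load a curated-evidence TSV (fixed header, one row per partner)."""
    import csv

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(CURATED_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise MalformedRecordError(
                f"{path}: curated table missing columns {sorted(missing)}"
            )
        for row in reader:
            entries.append(
                CuratedEntry(
                    partner_symbol=row["partner_symbol"].strip(),
                    partner_accession=row["partner_accession"].strip(),
                    partner_entry=row["partner_entry"].strip(),
                    year=int(row["year"]),
                    reference=row["reference"].strip(),
                    experimental_model=row["experimental_model"].strip(),
                    detection_method=row["detection_method"].strip(),
                    notes=row["notes"].strip(),
                    status=EntryStatus(row["status"].strip()),
                )
            )
    return CuratedInteractome(query_protein=query_protein, entries=entries)


def write_curated_table(
    interactome: CuratedInteractome, path: PathLike
) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(CURATED_COLUMNS)
        for e in interactome.entries:
            writer.writerow(
                [
                    e.partner_symbol,
                    e.partner_accession,
                    e.partner_entry,
                    e.year,
                    e.reference,
                    e.experimental_model,
                    e.detection_method,
                    e.notes,
                    e.status.value,
                ]
            )


class Category(Enum):
    SUPPORTED = "SUPPORTED"
    REJECTED = "REJECTED"
    UNVERIFIED = "UNVERIFIED"
    OUT_OF_SCOPE = "OUT_OF_SCOPE"


@dataclass
class CurationResult:
    """Classification of one merged interaction against the reference."""

    interaction: MergedInteraction
    category: Category
    matched_partner: str = ""
    via_symbol: bool = False
    note: str = ""

    COLUMNS = ("id_a", "id_b", "category", "matched_partner", "via_symbol",
               "note")

    def as_row(self) -> dict:
        return {
            "id_a": str(self.interaction.id_a),
            "id_b": str(self.interaction.id_b),
            "category": self.category.value,
            "matched_partner": self.matched_partner,
            "via_symbol": self.via_symbol,
            "note": self.note,
        }


def curate(
    merged: Iterable[MergedInteraction], reference: CuratedInteractome
) -> List[CurationResult]:
    """Classify merged interactions against the curated reference.

    Each record involving the query protein is SUPPORTED, REJECTED or
    UNVERIFIED according to the matching curated entry (accession match
    first; official-symbol fallback only for accession-less participants,
    annotated as lower confidence). Records not involving the query
    protein are OUT_OF_SCOPE. The four categories partition the input.
    """
    query = reference.query_protein
    if not is_valid_accession(query.primary_accession, extended=True):
        raise CurationError(
            f"query protein accession {query.primary_accession!r} is not "
            f"resolvable"
        )
    query_ids = {query.primary_accession, *query.secondary_accessions}
    results = []
    for record in merged:
        a_is_query = _matches_query(record.id_a, query, query_ids)
        b_is_query = _matches_query(record.id_b, query, query_ids)
        if not (a_is_query or b_is_query):
            results.append(
                CurationResult(
                    interaction=record,
                    category=Category.OUT_OF_SCOPE,
                    note="does not involve the query protein",
                )
            )
            continue
        partner = record.id_b if a_is_query else record.id_a
        results.append(
            _classify_partner(record, partner, reference, query_ids)
        )
    return results


def _matches_query(
    ident: Identifier, query: ProteinRecord, query_ids: set
) -> bool:
    if ident.is_accession and ident.value in query_ids:
        return True
    if ident.value == query.entry_name and query.entry_name:
        return True
    return False


def _classify_partner(
    record: MergedInteraction,
    partner: Identifier,
    reference: CuratedInteractome,
    query_ids: set,
) -> CurationResult:
    entry = None
    via_symbol = False
    if partner.is_accession:
        entry = reference.by_accession(partner.value)
    if entry is None and not partner.is_accession:
        # Symbol fallback, lower confidence. Canonicalisation during
        # merging may have promoted an unambiguous symbol to a gene id,
        # so also try the original member identifiers on the partner side.
        candidates = [partner.value]
        skip = query_ids | {reference.query_protein.entry_name}
        for member in record.members:
            for ident in (member.id_a, member.id_b):
                if ident.value not in skip and ident.value not in candidates:
                    candidates.append(ident.value)
        for candidate in candidates:
            entry = reference.by_symbol(candidate)
            if entry is not None:
                break
        via_symbol = entry is not None
    if entry is None:
        return CurationResult(
            interaction=record,
            category=Category.UNVERIFIED,
            note="no curated evidence for this partner",
        )
    category = (
        Category.SUPPORTED
        if entry.status is EntryStatus.SUPPORTED
        else Category.REJECTED
    )
    note = entry.notes
    if via_symbol:
        note = (note + "; " if note else "") + (
            "matched by symbol only (lower confidence)"
        )
    return CurationResult(
        interaction=record,
        category=category,
        matched_partner=entry.partner_symbol,
        via_symbol=via_symbol,
        note=note,
    )


# ---------------------------------------------------------------------------
# report output


def write_report(
    items: Sequence,
    path: PathLike,
    fmt: str = "tsv",
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write audit flags / merge results / curation results to TSV or JSON.

    Column order is deterministic (taken from the item class). An empty
    item list yields a header-only TSV (audit-flag columns by default) or
    an empty JSON array; JSON output reparses to the same row dicts.
    """
    import csv

    path = Path(path)
    if columns is None:
        columns = items[0].COLUMNS if items else AuditFlag.COLUMNS
    rows = [item.as_row() for item in items]
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=2, sort_keys=False)
            fh.write("\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unsupported report format {fmt!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([row[c] for c in columns])
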