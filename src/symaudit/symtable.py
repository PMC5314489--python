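"""Gene-symbol and protein tables: data model and CSV/TSV readers/writers.

The central objects are :class:`GeneTable` (HGNC-style rows: one gene with
its official symbol and literature synonyms) and :class:`ProteinTable`
(Swiss-Prot-style rows: primary accession, historical secondary accessions,
entry name). Both load from delimited text files through a small
column-mapping config so that differently-shaped exports (HGNC, UniProt,
in-house) can be consumed without rewriting the files.

Symbol handling is deliberately strict: comparisons downstream are exact and
case-sensitive, so the only normalisation applied on load is stripping
leading/trailing whitespace and removing exact duplicates within a single
gene's symbol set. No Unicode or Greek-letter folding is attempted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import yaml

from ._accession import is_valid_accession
from .errors import (
    DuplicateIdError,
    MalformedRecordError,
    MissingColumnError,
)

PathLike = Union[str, Path]


class LocusType(Enum):
    """Coarse locus classification; anything unrecognised maps to OTHER."""

    PROTEIN_CODING = "protein_coding"
    PSEUDOGENE = "pseudogene"
    OTHER = "other"

    @classmethod
    def parse(cls, raw: str) -> "LocusType":
        text = (raw or "").strip().lower().replace("-", "_").replace(" ", "_")
        if text in {"protein_coding", "protein_coding_gene", "coding"}:
            return cls.PROTEIN_CODING
        if text in {"pseudogene", "pseudo_gene", "pseudo", "pseudogenes"}:
            return cls.PSEUDOGENE
        return cls.OTHER


def _dedup(items: Sequence[str]) -> tuple:
    """Order-preserving exact (case-sensitive) deduplication."""
    seen = {}
    for item in items:
        if item and item not in seen:
            seen[item] = None
    return tuple(seen)


@dataclass
class GeneRecord:
    """One gene with its deduplicated accepted symbol set.

    ``symbols`` is the combined set the redundancy index is built from:
    the official symbol followed by the synonyms, with exact duplicates
    (including a synonym equal to the official symbol) removed.
    """

    gene_id: str
    official_symbol: str
    synonyms: tuple = ()
    locus_type: LocusType = LocusType.OTHER
    description: str = ""

    def __post_init__(self) -> None:
        self.gene_id = str(self.gene_id).strip()
        self.official_symbol = self.official_symbol.strip()
        if not self.gene_id:
            raise MalformedRecordError("gene_id must be non-empty")
        if not self.official_symbol:
            raise MalformedRecordError(
                f"gene {self.gene_id!r}: official_symbol must be non-empty"
            )
        cleaned = [s.strip() for s in self.synonyms]
        self.synonyms = tuple(
            s for s in _dedup(cleaned) if s != self.official_symbol
        )
        if isinstance(self.locus_type, str):
            self.locus_type = LocusType.parse(self.locus_type)

    @property
    def symbols(self) -> tuple:
        """Official symbol plus synonyms, exact-deduplicated, order kept."""
        return (self.official_symbol,) + self.synonyms


@dataclass
class ProteinRecord:
    """Primary accession plus its secondary-accession history.

    Secondary accessions are identifiers that were once citable but have
    been superseded; they still circulate in older literature, which is why
    the resolver redirects them instead of treating them as unknown.
    """

    primary_accession: str
    secondary_accessions: tuple = ()
    entry_name: str = ""
    description: str = ""
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.primary_accession = self.primary_accession.strip()
        if not is_valid_accession(self.primary_accession, extended=True):
            raise MalformedRecordError(
                f"invalid primary accession {self.primary_accession!r}"
            )
        cleaned = [a.strip() for a in self.secondary_accessions]
        self.secondary_accessions = tuple(
            a for a in _dedup(cleaned) if a != self.primary_accession
        )
        for acc in self.secondary_accessions:
            if not is_valid_accession(acc, extended=True):
                raise MalformedRecordError(
                    f"{self.primary_accession}: invalid secondary accession "
                    f"{acc!r}"
                )
        self.entry_name = self.entry_name.strip()
        if self.entry_name:
            parts = self.entry_name.split("_")
            if len(parts) != 2 or not all(parts):
                raise MalformedRecordError(
                    f"{self.primary_accession}: entry name "
                    f"{self.entry_name!r} must be MNEMONIC_SPECIES with "
                    f"exactly one underscore"
                )
        if self.gene_id is not None:
            self.gene_id = str(self.gene_id).strip() or None

    @property
    def accessions(self) -> tuple:
        """Primary accession followed by all secondaries."""
        return (self.primary_accession,) + self.secondary_accessions


@dataclass
class GeneTable:
    records: list = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise DuplicateIdError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
        self._by_id = {rec.gene_id: rec for rec in self.records}

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, gene_id: str) -> Optional[GeneRecord]:
        return self._by_id.get(gene_id)

    def filtered(self, locus_type: Optional[LocusType]) -> "GeneTable":
        """Sub-table keeping only records of the given locus type."""
        if locus_type is None:
            return self
        kept = [r for r in self.records if r.locus_type == locus_type]
        return GeneTable(records=kept, source_label=self.source_label)


@dataclass
class ProteinTable:
    records: list = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        self._by_primary = {}
        secondary_owner = {}
        for rec in self.records:
            if rec.primary_accession in self._by_primary:
                raise DuplicateIdError(
                    f"duplicate primary accession {rec.primary_accession!r}"
                )
            self._by_primary[rec.primary_accession] = rec
        for rec in self.records:
            for acc in rec.secondary_accessions:
                if acc in self._by_primary:
                    raise MalformedRecordError(
                        f"accession {acc!r} is primary in one record and "
                        f"secondary under {rec.primary_accession!r}"
                    )
                if acc in secondary_owner:
                    raise MalformedRecordError(
                        f"secondary accession {acc!r} claimed by both "
                        f"{secondary_owner[acc]!r} and "
                        f"{rec.primary_accession!r}"
                    )
                secondary_owner[acc] = rec.primary_accession
        self._secondary_owner = secondary_owner
        self._by_entry = {r.entry_name: r for r in self.records if r.entry_name}
        self._by_gene = {}
        for rec in self.records:
            if rec.gene_id and rec.gene_id not in self._by_gene:
                self._by_gene[rec.gene_id] = rec

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_primary(self, accession: str) -> Optional[ProteinRecord]:
        return self._by_primary.get(accession)

    def primary_for_secondary(self, accession: str) -> Optional[str]:
        return self._secondary_owner.get(accession)

    def by_entry_name(self, entry_name: str) -> Optional[ProteinRecord]:
        return self._by_entry.get(entry_name)

    def by_gene_id(self, gene_id: str) -> Optional[ProteinRecord]:
        return self._by_gene.get(gene_id)


# ---------------------------------------------------------------------------
# column mappings


@dataclass
class GeneColumns:
    """Column mapping for gene tables; loadable from a YAML/JSON config."""

    gene_id: str = "gene_id"
    symbol: str = "symbol"
    synonyms: str = "synonyms"
    locus_type: Optional[str] = "locus_type"
    description: Optional[str] = "description"
    synonym_delimiter: str = ";"
    fallback_delimiters: tuple = ("|",)

    @classmethod
    def from_file(cls, path: PathLike) -> "GeneColumns":
        return cls(**_load_mapping(path, cls))


@dataclass
class ProteinColumns:
    accession: str = "accession"
    secondary_accessions: str = "secondary_accessions"
    entry_name: str = "entry_name"
    description: Optional[str] = "description"
    gene_id: Optional[str] = "gene_id"
    accession_delimiter: str = ";"
    fallback_delimiters: tuple = ("|",)

    @classmethod
    def from_file(cls, path: PathLike) -> "ProteinColumns":
        return cls(**_load_mapping(path, cls))


def _load_mapping(path: PathLike, cls) -> dict:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise MalformedRecordError(f"{path}: column mapping must be a mapping")
    valid = {f.name for f in fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise MissingColumnError(
            f"{path}: unknown column-mapping keys {sorted(unknown)}"
        )
    if "fallback_delimiters" in raw and raw["fallback_delimiters"] is not None:
        raw["fallback_delimiters"] = tuple(raw["fallback_delimiters"])
    return raw


def _split_multi(cell: str, delimiter: str, fallbacks: Sequence[str]) -> list:
    """Split a multi-value cell on the primary delimiter, falling back to
    the first alternative delimiter actually present in the cell."""
    cell = (cell or "").strip()
    if not cell:
        return []
    if delimiter in cell:
        return cell.split(delimiter)
    for alt in fallbacks:
        if alt in cell:
            return cell.split(alt)
    return [cell]


def _sniff_delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _open_reader(path: Path, delimiter: Optional[str]):
    fh = open(path, newline="", encoding="utf-8")
    return fh, csv.DictReader(fh, delimiter=_sniff_delimiter(path, delimiter))


def _require_columns(reader: csv.DictReader, wanted: dict, path: Path) -> None:
    header = reader.fieldnames or []
    for role, name in wanted.items():
        if name is not None and name not in header:
            raise MissingColumnError(
                f"{path}: mapped column {name!r} (for {role}) not in header "
                f"{header}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_gene_table(
    path: PathLike,
    columns: Optional[GeneColumns] = None,
    delimiter: Optional[str] = None,
    source_label: Optional[str] = None,
) -> GeneTable:
    """Load a gene-symbol table from a delimited text file.

    Each data row becomes one :class:`GeneRecord`; the per-gene symbol set
    is deduplicated on load. Rows with an empty gene id, duplicate gene
    ids, or a missing mapped column raise an error naming the offender.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    cols = columns or GeneColumns()
    fh, reader = _open_reader(path, delimiter)
    with fh:
        _require_columns(
            reader,
            {
                "gene_id": cols.gene_id,
                "symbol": cols.symbol,
                "synonyms": cols.synonyms,
                "locus_type": cols.locus_type,
                "description": cols.description,
            },
            path,
        )
        records = []
        for lineno, row in enumerate(reader, start=2):
            gene_id = (row.get(cols.gene_id) or "").strip()
            if not gene_id:
                raise MalformedRecordError(f"{path}:{lineno}: empty gene_id")
            synonyms = _split_multi(
                row.get(cols.synonyms) or "",
                cols.synonym_delimiter,
                cols.fallback_delimiters,
            )
            try:
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        official_symbol=(row.get(cols.symbol) or ""),
                        synonyms=tuple(synonyms),
                        locus_type=LocusType.parse(
                            row.get(cols.locus_type) or ""
                        )
                        if cols.locus_type
                        else LocusType.OTHER,
                        description=(row.get(cols.description) or "").strip()
                        if cols.description
                        else "",
                    )
                )
            except MalformedRecordError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
    label = source_label if source_label is not None else str(path)
    return GeneTable(records=records, source_label=label)


def read_protein_table(
    path: PathLike,
    columns: Optional[ProteinColumns] = None,
    delimiter: Optional[str] = None,
    source_label: Optional[str] = None,
) -> ProteinTable:
    """Load a protein table (primary/secondary accessions, entry names)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    cols = columns or ProteinColumns()
    fh, reader = _open_reader(path, delimiter)
    with fh:
        _require_columns(
            reader,
            {
                "accession": cols.accession,
                "secondary_accessions": cols.secondary_accessions,
                "entry_name": cols.entry_name,
                "description": cols.description,
                "gene_id": cols.gene_id,
            },
            path,
        )
        records = []
        for lineno, row in enumerate(reader, start=2):
            secondaries = _split_multi(
                row.get(cols.secondary_accessions) or "",
                cols.accession_delimiter,
                cols.fallback_delimiters,
            )
            try:
                records.append(
                    ProteinRecord(
                        primary_accession=(row.get(cols.accession) or ""),
                        secondary_accessions=tuple(secondaries),
                        entry_name=(row.get(cols.entry_name) or ""),
                        description=(row.get(cols.description) or "").strip()
                        if cols.description
                        else "",
                        gene_id=(row.get(cols.gene_id) or None)
                        if cols.gene_id
                        else None,
                    )
                )
            except MalformedRecordError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
    label = source_label if source_label is not None else str(path)
    return ProteinTable(records=records, source_label=label)


def write_gene_table(
    table: GeneTable,
    path: PathLike,
    columns: Optional[GeneColumns] = None,
    delimiter: Optional[str] = None,
) -> None:
    """Write a gene table back to CSV/TSV (RFC-4180 quoting)."""
    path = Path(path)
    cols = columns or GeneColumns()
    sep = _sniff_delimiter(path, delimiter)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, quoting=csv.QUOTE_MINIMAL)
        header = [cols.gene_id, cols.symbol, cols.synonyms]
        if cols.locus_type:
            header.append(cols.locus_type)
        if cols.description:
            header.append(cols.description)
        writer.writerow(header)
        for rec in table:
            row = [
                rec.gene_id,
                rec.official_symbol,
                cols.synonym_delimiter.join(rec.synonyms),
            ]
            if cols.locus_type:
                row.append(rec.locus_type.value)
            if cols.description:
                row.append(rec.description)
            writer.writerow(row)


def write_protein_table(
    table: ProteinTable,
    path: PathLike,
    columns: Optional[ProteinColumns] = None,
    delimiter: Optional[str] = None,
) -> None:
    path = Path(path)
    cols = columns or ProteinColumns()
    sep = _sniff_delimiter(path, delimiter)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, quoting=csv.QUOTE_MINIMAL)
        header = [cols.accession, cols.secondary_accessions, cols.entry_name]
        if cols.description:
            header.append(cols.description)
        if cols.gene_id:
            header.append(cols.gene_id)
        writer.writerow(header)
        for rec in table:
            row = [
                rec.primary_accession,
                cols.accession_delimiter.join(rec.secondary_accessions),
                rec.entry_name,
            ]
            if cols.description:
                row.append(rec.description)
            if cols.gene_id:
                row.append(rec.gene_id or "")
            writer.writerow(row)


def search_descriptions(
    table: GeneTable, needle: str, case_sensitive: bool = False
) -> list:
    """Gene ids whose description contains *needle* as a substring.

    This is deliberately a separate, lower-confidence lookup than symbol
    resolution: free-text descriptions routinely mention other proteins
    (e.g. an enzyme-family abbreviation appearing in dozens of entries), so
    hits here are leads for manual curation, not identifications.
    """
    if not needle:
        raise ValueError("search needle must be non-empty")
    if case_sensitive:
        return [r.gene_id for r in table if needle in r.description]
    folded = needle.lower()
    return [r.gene_id for r in table if folded in r.description.lower()]
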