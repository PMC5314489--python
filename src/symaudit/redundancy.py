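"""Symbol redundancy: inverted index, per-symbol degree, histogram, checker.

A gene symbol is *redundant* when it belongs to the accepted symbol set
(official symbol plus synonyms) of two or more distinct genes. The degree
of a symbol is the number of distinct genes carrying it; degree >= 2 makes
the symbol ambiguous, and ambiguous symbols are the dominant cause of
false positives when interaction databases are queried by gene name.

All comparisons are exact and case-sensitive by default. An opt-in
case-folding mode uppercases symbols at index-build time for users who
want a looser audit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

from .errors import EmptyIndexError
from .symtable import GeneTable, LocusType


@dataclass
class SymbolIndex:
    """Inverted symbol -> gene_id mapping.

    ``entries`` maps each symbol to the tuple of distinct gene ids carrying
    it, in table order. ``locus_filter`` records any restriction applied at
    build time (e.g. protein-coding only); ``case_fold`` records whether
    symbols were uppercased before indexing.
    """

    entries: dict
    locus_filter: Optional[LocusType] = None
    case_fold: bool = False

    def degree(self, symbol: str) -> int:
        key = symbol.upper() if self.case_fold else symbol
        return len(self.entries.get(key, ()))

    def genes_for(self, symbol: str) -> tuple:
        key = symbol.upper() if self.case_fold else symbol
        return tuple(self.entries.get(key, ()))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RedundancyHistogram:
    """Counts of symbols at each redundancy degree N (sparse: no zero bins).

    ``bins[N]`` is the number of distinct symbols carried by exactly N
    distinct genes. The conserved quantity is sum(bins.values()) ==
    number of distinct symbols in the index.
    """

    bins: dict

    @property
    def total_symbols(self) -> int:
        return sum(self.bins.values())

    @property
    def max_degree(self) -> int:
        return max(self.bins) if self.bins else 0

    def rows(self, fill_zeros: bool = False) -> List[tuple]:
        """(N, count) pairs sorted by N; optionally dense from 1..max."""
        if fill_zeros and self.bins:
            return [(n, self.bins.get(n, 0)) for n in range(1, self.max_degree + 1)]
        return sorted(self.bins.items())


@dataclass
class CheckerRow:
    """One queried symbol: its degree, the genes sharing it, and for each
    sharing gene the full alternative symbol set plus whether the match hit
    the official symbol or a synonym."""

    symbol: str
    degree: int
    sharing_genes: tuple
    match_kinds: tuple
    alternatives: tuple


@dataclass
class CheckerReport:
    rows: list = field(default_factory=list)

    COLUMNS = ("symbol", "degree", "gene_ids", "match_kind", "alternatives")

    def as_rows(self) -> List[dict]:
        out = []
        for row in self.rows:
            out.append(
                {
                    "symbol": row.symbol,
                    "degree": row.degree,
                    "gene_ids": ",".join(row.sharing_genes),
                    "match_kind": ",".join(row.match_kinds),
                    "alternatives": "|".join(
                        ";".join(alt) for alt in row.alternatives
                    ),
                }
            )
        return out


def build_index(
    table: GeneTable,
    locus_filter: Optional[LocusType] = None,
    case_fold: bool = False,
) -> SymbolIndex:
    """Build the inverted symbol index over a gene table.

    Official symbols and synonyms contribute identically: each member of a
    gene's combined symbol set yields one (symbol -> gene_id) entry. The
    per-gene set is already deduplicated, so one gene never counts twice
    for the same symbol even under case folding.
    """
    filtered = table.filtered(locus_filter)
    if len(filtered) == 0:
        raise EmptyIndexError(
            f"no genes left after locus filter {locus_filter}"
        )
    entries: dict = {}
    for rec in filtered:
        symbols = rec.symbols
        if case_fold:
            seen = {}
            for s in symbols:
                seen.setdefault(s.upper(), None)
            symbols = tuple(seen)
        for symbol in symbols:
            bucket = entries.setdefault(symbol, {})
            bucket.setdefault(rec.gene_id, None)
    frozen = {sym: tuple(genes) for sym, genes in entries.items()}
    return SymbolIndex(entries=frozen, locus_filter=locus_filter,
                       case_fold=case_fold)


def redundancy_degree(index: SymbolIndex, symbol: str) -> int:
    """Number of distinct genes whose symbol set contains *symbol*.

    An absent symbol has degree 0 — not an error, because the checker's
    use case is auditing arbitrary pasted lists.
    """
    return index.degree(symbol)


def redundancy_histogram(index: SymbolIndex) -> RedundancyHistogram:
    """Degree histogram over all symbols in the index."""
    if not index.entries:
        raise EmptyIndexError("cannot build a histogram from an empty index")
    counts = Counter(len(genes) for genes in index.entries.values())
    return RedundancyHistogram(bins=dict(sorted(counts.items())))


def check_symbols(
    index: SymbolIndex, table: GeneTable, symbols: Iterable[str]
) -> CheckerReport:
    """Redundancy report for a pasted list of symbols.

    One row per unique queried symbol, preserving first-occurrence order.
    Each row lists the sharing genes and, per gene, its full combined
    symbol set (the alternatives a curator should consider) plus whether
    the query matched that gene's official symbol or a synonym.
    """
    queried = list(symbols)
    if not queried:
        raise ValueError("symbol query list must be non-empty")
    unique = {}
    for s in queried:
        unique.setdefault(s, None)
    rows = []
    for symbol in unique:
        gene_ids = index.genes_for(symbol)
        kinds = []
        alternatives = []
        for gid in gene_ids:
            rec = table.get(gid)
            if rec is None:  # index built from a different table
                kinds.append("unknown")
                alternatives.append(())
                continue
            if index.case_fold:
                official = rec.official_symbol.upper() == symbol.upper()
            else:
                official = rec.official_symbol == symbol
            kinds.append("official" if official else "synonym")
            alternatives.append(rec.symbols)
        rows.append(
            CheckerRow(
                symbol=symbol,
                degree=len(gene_ids),
                sharing_genes=gene_ids,
                match_kinds=tuple(kinds),
                alternatives=tuple(alternatives),
            )
        )
    return CheckerReport(rows=rows)
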