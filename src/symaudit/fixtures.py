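"""Bundled reference fixtures and a seeded synthetic gene-table generator.

Two sources of test data, neither requiring any download:

* :func:`load_bundle` ships a small curated bundle built from values
  reported in the published literature on identifier ambiguity and the
  DREAM (KCNIP3/calsenilin) interactome: the choline-kinase synonym
  family, the eleven GeneIDs sharing the PPIASE abbreviation, the
  uromodulin accession history, and the row-for-row curated DREAM
  evidence table with its rejected false-positive list. Entries whose
  details were never individually reported (official symbols of the
  PPIASE-family genes, the pseudogene row, the CSNK1AIL gene id) are
  synthetic placeholders and are marked as such in the data files.

* :func:`generate_table` builds synthetic gene tables whose symbol
  redundancy histogram is controlled *exactly*, so redundancy
  computations can be property-tested against a known ground truth at
  any scale.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .audit import CuratedInteractome, read_curated_table, read_mitab
from .errors import InfeasibleSpecError
from .symtable import (
    GeneColumns,
    GeneRecord,
    GeneTable,
    LocusType,
    ProteinColumns,
    ProteinTable,
    read_gene_table,
    read_protein_table,
)

_DATA = resources.files("symaudit") / "data"

GENE_FIXTURE = "fixture_genes.csv"
PROTEIN_FIXTURE = "fixture_proteins.csv"
CURATED_FIXTURE = "dream_curated.tsv"
MITAB_FIXTURE = "dream.mitab"

#: Query protein of the bundled curated interactome.
DREAM_ACCESSION = "Q9Y2W7"


@dataclass
class FixtureBundle:
    genes: GeneTable
    proteins: ProteinTable
    curated: CuratedInteractome
    mitab_path: Path


def _data_path(name: str) -> Path:
    path = _DATA / name
    with resources.as_file(path) as concrete:
        return Path(concrete)


def load_bundle() -> FixtureBundle:
    """Load the bundled gene/protein/curated/MITAB fixtures."""
    genes = read_gene_table(_data_path(GENE_FIXTURE),
                            source_label="bundled gene fixture")
    proteins = read_protein_table(_data_path(PROTEIN_FIXTURE),
                                  source_label="bundled protein fixture")
    query = proteins.by_primary(DREAM_ACCESSION)
    curated = read_curated_table(_data_path(CURATED_FIXTURE), query)
    return FixtureBundle(
        genes=genes,
        proteins=proteins,
        curated=curated,
        mitab_path=_data_path(MITAB_FIXTURE),
    )


def export_fixtures(directory) -> list:
    """Copy the bundled fixture files into *directory* for inspection."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (GENE_FIXTURE, PROTEIN_FIXTURE, CURATED_FIXTURE,
                 MITAB_FIXTURE):
        target = directory / name
        target.write_text(_data_path(name).read_text(encoding="utf-8"),
                          encoding="utf-8")
        written.append(target)
    return written


# ---------------------------------------------------------------------------
# synthetic generator


@dataclass
class RedundancySpec:
    """Target structure for a synthetic gene table.

    ``target_histogram`` maps redundancy degree N to the number of symbols
    that must be carried by exactly N distinct genes. ``symbols_per_gene``
    bounds how many symbols each synthetic gene may carry (inclusive
    range). The spec is feasible iff every N fits within ``n_genes`` genes
    and the total symbol-slot demand sum(N * count) lies between
    ``n_genes * min`` and ``n_genes * max``.
    """

    target_histogram: dict
    n_genes: int
    symbols_per_gene: tuple = (1, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_histogram = {
            int(n): int(c) for n, c in self.target_histogram.items() if c
        }
        lo, hi = self.symbols_per_gene
        if self.n_genes < 1:
            raise InfeasibleSpecError("n_genes must be >= 1")
        if lo < 1 or hi < lo:
            raise InfeasibleSpecError(
                f"symbols_per_gene range {self.symbols_per_gene} invalid"
            )
        for n, count in self.target_histogram.items():
            if n < 1:
                raise InfeasibleSpecError(f"degree {n} < 1 in histogram")
            if count < 0:
                raise InfeasibleSpecError(f"negative count for degree {n}")
            if n > self.n_genes:
                raise InfeasibleSpecError(
                    f"degree {n} exceeds n_genes={self.n_genes}: a symbol "
                    f"cannot be shared by more genes than exist"
                )
        slots = self.total_slots
        if slots > self.n_genes * hi:
            raise InfeasibleSpecError(
                f"symbol-slot demand {slots} exceeds capacity "
                f"{self.n_genes} genes x {hi} symbols"
            )
        if slots < self.n_genes * lo:
            raise InfeasibleSpecError(
                f"symbol-slot demand {slots} below the minimum "
                f"{self.n_genes} genes x {lo} symbols; the histogram would "
                f"leave genes without a symbol"
            )

    @property
    def total_slots(self) -> int:
        return sum(n * c for n, c in self.target_histogram.items())

    @property
    def total_symbols(self) -> int:
        return sum(self.target_histogram.values())


def generate_table(spec: RedundancySpec) -> GeneTable:
    """Build a synthetic gene table realising *spec* exactly.

    Construction is rejection-free: shared symbols are allocated first
    (each degree-N symbol is assigned to the N least-loaded genes, random
    tie-break), then degree-1 symbols fill the remaining capacity. Because
    minted symbol strings are globally unique, the redundancy histogram of
    the output equals ``spec.target_histogram`` by construction, and the
    same seed always yields a byte-identical table.
    """
    rng = random.Random(spec.seed)
    lo, hi = spec.symbols_per_gene
    n = spec.n_genes
    loads = [0] * n
    assigned = [[] for _ in range(n)]  # symbols per gene, in order
    tiebreak = [rng.random() for _ in range(n)]
    counter = 0

    def mint() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:06d}"

    def pick(k: int) -> list:
        order = sorted(range(n), key=lambda i: (loads[i], tiebreak[i], i))
        chosen = [i for i in order if loads[i] < hi][:k]
        if len(chosen) < k:
            raise InfeasibleSpecError(
                f"could not place a degree-{k} symbol: only {len(chosen)} "
                f"genes below capacity {hi}"
            )
        return chosen

    # Shared symbols first, largest degree first, so balancing has room.
    for degree in sorted(spec.target_histogram, reverse=True):
        if degree == 1:
            continue
        for _ in range(spec.target_histogram[degree]):
            symbol = mint()
            for i in pick(degree):
                assigned[i].append(symbol)
                loads[i] += 1
            # refresh tie-break keys so sharing patterns vary
            for i in range(n):
                tiebreak[i] = rng.random()
    for _ in range(spec.target_histogram.get(1, 0)):
        symbol = mint()
        i = pick(1)[0]
        assigned[i].append(symbol)
        loads[i] += 1
        tiebreak[i] = rng.random()
    short = [i for i in range(n) if loads[i] < lo]
    if short:
        raise InfeasibleSpecError(
            f"{len(short)} genes ended below the minimum of {lo} symbols; "
            f"add degree-1 symbols to the histogram"
        )

    records = []
    for i in range(n):
        symbols = assigned[i]
        records.append(
            GeneRecord(
                gene_id=f"G{i + 1:05d}",
                official_symbol=symbols[0],
                synonyms=tuple(symbols[1:]),
                locus_type=LocusType.PROTEIN_CODING,
                description=f"synthetic gene {i + 1}",
            )
        )
    return GeneTable(
        records=records,
        source_label=f"synthetic(seed={spec.seed})",
    )
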