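"""Shared fixtures and independent brute-force oracles.

The oracles here recompute redundancy quantities by direct nested scans
over the table, deliberately bypassing the inverted index, so index-based
results can be checked against an implementation-independent path.
"""

import random
from collections import Counter

import pytest

from symaudit import GeneRecord, GeneTable, LocusType, load_bundle


@pytest.fixture(scope="session")
def bundle():
    return load_bundle()


@pytest.fixture(scope="session")
def gene_table(bundle):
    return bundle.genes


@pytest.fixture(scope="session")
def protein_table(bundle):
    return bundle.proteins


# ---------------------------------------------------------------------------
# oracles


def brute_degree(table, symbol):
    """Degree of *symbol* by scanning every gene's symbol set."""
    return sum(1 for rec in table if symbol in rec.symbols)


def brute_histogram(table):
    """Degree histogram by recomputing every symbol's degree independently."""
    symbols = []
    seen = set()
    for rec in table:
        for s in rec.symbols:
            if s not in seen:
                seen.add(s)
                symbols.append(s)
    return dict(Counter(brute_degree(table, s) for s in symbols))


# ---------------------------------------------------------------------------
# random table construction (independent of the package's generator)


def random_gene_table(rng: random.Random, max_genes: int = 300) -> GeneTable:
    """A random gene table with a small symbol pool to force collisions."""
    n = rng.randint(2, max_genes)
    pool = [f"SYM{i}" for i in range(max(3, n // 2))]
    records = []
    for i in range(n):
        official = rng.choice(pool)
        synonyms = rng.sample(pool, k=rng.randint(0, min(4, len(pool))))
        records.append(
            GeneRecord(
                gene_id=str(i + 1),
                official_symbol=official,
                synonyms=tuple(synonyms),
                locus_type=rng.choice(
                    [LocusType.PROTEIN_CODING, LocusType.PSEUDOGENE]
                ),
                description=f"random gene {i}",
            )
        )
    return GeneTable(records=records, source_label="random")
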