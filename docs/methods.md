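# Methods

## Model

A gene *g* carries an accepted symbol set symbols(*g*): its official
symbol plus the synonyms in use in the literature, deduplicated by exact
case-sensitive string comparison within the gene. The redundancy degree of
a symbol *s* over a gene table *T* is

    deg(s) = |{ g in T : s in symbols(g) }|

computed over official symbols and synonyms pooled — authors use either
interchangeably, so both must count. The redundancy histogram maps each
degree N ≥ 1 to the number of distinct symbols with exactly that degree;
its bins sum to the number of distinct symbols in the table (the
conservation invariant the tests enforce). Degree 0 (a queried symbol
absent from the table) is a valid checker result, not an error: the
intended use is auditing arbitrary pasted symbol lists.

Protein identifiers follow a two-tier scheme. An **accession** is six
consecutive uppercase alphanumeric characters, first character alphabetic;
it is the stable, citable identifier. A protein may additionally carry
**secondary** accessions — identifiers that were citable in earlier
database releases and still circulate in older papers; the resolver maps
them to the current primary (`secondary_redirect`) rather than treating
them as unknown. **Entry names** (`MNEMONIC_SPECIES`, e.g. `CHKA_HUMAN`)
are human-readable but may change between releases; they resolve by exact
match only and the resolution note flags the weaker stability. Resolution
is a total trichotomy: every query returns exactly one of unknown /
unambiguous / ambiguous (plus the redirect case for accessions), with the
target count determined by the status.

## Interaction auditing and curation

MITAB input uses the minimal 15-column PSI-MITAB 2.5 layout; columns 1–2
(namespaced interactor ids), 7 (detection method), 9 (publication) and 13
(source database) are consumed, all columns pass through round trips.
Auditing is total and per-participant: symbol-namespace ids are checked
against the redundancy index (degree ≥ 2 → `AMBIGUOUS_SYMBOL`, 0 →
`UNKNOWN_SYMBOL`), accession-namespace ids against the lexical rule and
the secondary-accession map (`MALFORMED_ACCESSION`, `SECONDARY_ACCESSION`).
Other namespaces are out of audit scope.

Multi-source merging canonicalises each participant first: secondary
accessions are replaced by their primary, and a symbol carried by exactly
one gene is promoted to that gene's protein accession. The merge key is
the unordered canonical pair. A record with any unresolved participant
(ambiguous or unknown symbol, malformed accession, undeclared namespace)
additionally keys on its source database, so such records collapse within
one source but never across sources — merging on an ambiguous symbol is
precisely the error this tool audits, and refusing it keeps the operation
idempotent: re-merging a merged list is a fixed point, and the result is
invariant under input-list order.

Curation classifies each merged record against a reference of curated
evidence rows. Records not involving the query protein are OUT_OF_SCOPE;
otherwise the partner is matched by accession first, falling back to the
official symbol (including the original pre-canonicalisation identifiers
of the merged members) only for accession-less participants, with the
fallback annotated as lower confidence. Matches inherit the entry's
status (SUPPORTED / REJECTED); everything else is UNVERIFIED. The four
categories partition the input. Self-interactions are retained: curated
tables legitimately document multimers.

## Parameters that matter

- `case_fold` (index build, default off): uppercase symbols before
  comparison. Off by default because the symbol contract is
  case-sensitive; "Chka" and "CHKA" are distinct strings.
- `extended` accession validation (default off): additionally accepts the
  ten-character accession form. Off so that the default contract is the
  strict six-character rule.
- `locus_filter`: restricts index building to one locus class; redundancy
  statistics over protein-coding genes are the headline quantity, but
  pseudogene symbols are retained in the tables.
- `strict`/`lenient` MITAB parsing: strict (default) raises on the first
  unparseable line with its line number; lenient skips and logs.
- Synonym-cell delimiter: semicolon, falling back to pipe, configurable
  per file via the YAML/JSON column mapping — differently-shaped exports
  load without editing the data.

## Synthetic generator

`generate_table(RedundancySpec)` emulates a gene table whose redundancy
structure is known exactly: the spec fixes the target histogram, the gene
count and a per-gene symbol-capacity range. Shared symbols are allocated
first (largest degree first, each to the least-loaded distinct genes with
seeded random tie-breaks), then degree-1 symbols fill remaining capacity;
minted symbol strings are globally unique, so the output's histogram
equals the spec by construction and infeasible specs (degree exceeding
the gene count, slot demand outside `n_genes × [min, max]`) fail fast
with the violated bound named. The same seed yields byte-identical
tables; the seed is recorded in the table's source label.

What the generator does **not** emulate: realistic symbol morphology
(family prefixes, Greek letters), correlation between locus type and
synonym count, description text. Passing the round-trip and oracle
properties therefore demonstrates correctness of the counting machinery,
not robustness to the orthographic messiness of real nomenclature.

## Bundled fixtures

The bundle reproduces identifier families documented in the published
literature: the five choline-kinase-alpha abbreviations, the eleven
GeneIDs sharing the synonym PPIASE, the uromodulin accession history
(P07911 with three superseded secondaries), and the curated DREAM
(KCNIP3, Q9Y2W7) interactome — 22 supported evidence rows plus a rejected
list of database false positives (RCC1 and six casein-kinase symbols,
one of which is stored verbatim as the database printed it). Values not
individually documented (official symbols of the PPIASE-family genes, the
pseudogene row, citation tokens) are synthetic placeholders and say so in
the data files. The rejected casein-kinase entries carry no accession —
only their symbols were ever listed — which is the one place the
accession-required rule for curated entries is relaxed.

Note one documented oddity kept as-is: the PPIASE family is described in
the source material as "ten" genes while eleven GeneIDs are listed; the
fixture stores all eleven and the tests assert degree 11.

## Numerical / procedural choices

- Symbol comparison: exact byte equality after stripping leading/trailing
  whitespace; internal whitespace distinguishes symbols; no Unicode or
  Greek-letter normalisation ("α" ≠ "alpha") — a known limitation.
- Histogram storage is sparse (no zero bins); display/export densifies on
  request (`--fill-zeros`).
- Checker reports deduplicate queries to first occurrence, preserving
  paste order.
- Merge output order: lexicographic in the canonical pair, for
  deterministic reports.
- Problem sizes in the test suite and acceptance script — 100 random
  tables of ≤ 300 genes for oracle equivalence, 50 random feasible specs
  for the generator round trip — were chosen as comfortably exceeding the
  regime where counting errors would appear while keeping the default
  suite fast.

## Limitations

- The full-genome symbol tables (tens of thousands of genes) are not
  bundled; table-scale count checks run only when the full supplementary
  exports are placed under `data/supplementary/`.
- No fuzzy or approximate symbol matching, no cross-species mapping, no
  live database queries; the toolkit is deliberately offline and exact.
- Entry-name resolution is an interpretation (exact match), since entry
  names are not guaranteed stable across releases.
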