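"""MITAB I/O, ambiguity flagging, multi-source merging, and curation."""

import itertools
import json
import random

import pytest

from symaudit import (
    Category,
    CuratedEntry,
    CuratedInteractome,
    FlagType,
    GeneRecord,
    GeneTable,
    Identifier,
    ProteinRecord,
    ProteinTable,
    audit_interactions,
    build_index,
    curate,
    merge_sources,
    read_mitab,
    write_mitab,
    write_report,
)
from symaudit.audit import AuditFlag, InteractionRecord
from symaudit.errors import CurationError, MitabParseError


def rec(a, b, source="dbA", pub="pub:1", line=1, method=""):
    return InteractionRecord(
        id_a=Identifier.parse(a),
        id_b=Identifier.parse(b),
        source_db=source,
        publication=pub,
        detection_method=method,
        raw_line_no=line,
    )


@pytest.fixture(scope="module")
def index(bundle):
    return build_index(bundle.genes)


class TestMitabIO:
    def test_parse_namespaced_ids_and_provenance(self, tmp_path):
        path = tmp_path / "x.mitab"
        cols = ["uniprotkb:P35790", "uniprotkb:P19835", "-", "-", "-", "-",
                "two hybrid", "-", "pubmed:123", "-", "-", "-", "intact",
                "-", "-"]
        path.write_text("\t".join(cols) + "\n")
        (record,) = read_mitab(path)
        assert record.id_a == Identifier("uniprotkb", "P35790")
        assert record.id_b == Identifier("uniprotkb", "P19835")
        assert record.detection_method == "two hybrid"
        assert record.publication == "pubmed:123"
        assert record.source_db == "intact"
        assert record.raw_line_no == 1

    def test_comment_and_blank_lines_skipped(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text(
            "# header comment\n\nuniprotkb:P35790\tgenesymbol:CK\n"
        )
        records = read_mitab(path)
        assert len(records) == 1
        assert records[0].raw_line_no == 3

    def test_symbol_namespace_round_trips(self, tmp_path):
        src = tmp_path / "in.mitab"
        src.write_text("genesymbol:CK\tuniprotkb:P35790\n")
        records = read_mitab(src)
        out = tmp_path / "out.mitab"
        write_mitab(records, out)
        reread = read_mitab(out)
        assert reread[0].id_a == Identifier("genesymbol", "CK")
        assert reread[0].id_b == records[0].id_b

    def test_unknown_namespace_preserved_and_tagged(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text("weirddb:XYZ\tuniprotkb:P35790\n")
        (record,) = read_mitab(path)
        assert record.id_a.namespace == "weirddb"
        assert not record.id_a.known

    def test_strict_mode_errors_with_line_number(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text("uniprotkb:P35790\tuniprotkb:P19835\nonlyonecolumn\n")
        with pytest.raises(MitabParseError, match=":2"):
            read_mitab(path, strict=True)

    def test_lenient_mode_skips_bad_lines(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text("uniprotkb:P35790\tuniprotkb:P19835\nonlyonecolumn\n")
        records = read_mitab(path, strict=False)
        assert len(records) == 1

    def test_bundled_mitab_loads(self, bundle):
        records = read_mitab(bundle.mitab_path)
        assert len(records) == 22
        assert all(r.id_a.value == "Q9Y2W7" for r in records)


class TestAuditFlags:
    def test_ambiguous_symbol_lists_candidate_genes(self, bundle, index):
        flags = audit_interactions(
            [rec("uniprotkb:P35790", "genesymbol:CK")],
            index, bundle.proteins,
        )
        (flag,) = flags
        assert flag.flag is FlagType.AMBIGUOUS_SYMBOL
        assert flag.participant == "B"
        # both the choline kinase and casein kinase genes must be named
        assert "1119" in flag.detail and "1457" in flag.detail

    def test_secondary_accession_flag_names_primary(self, bundle, index):
        flags = audit_interactions(
            [rec("uniprotkb:Q540J6", "uniprotkb:P35790")],
            index, bundle.proteins,
        )
        (flag,) = flags
        assert flag.flag is FlagType.SECONDARY_ACCESSION
        assert "P07911" in flag.detail

    def test_clean_primary_pair_yields_no_flags(self, bundle, index):
        flags = audit_interactions(
            [rec("uniprotkb:P35790", "uniprotkb:P07911")],
            index, bundle.proteins,
        )
        assert flags == []

    def test_malformed_accession_flagged(self, bundle, index):
        flags = audit_interactions(
            [rec("uniprotkb:P35 790", "uniprotkb:P07911")],
            index, bundle.proteins,
        )
        assert [f.flag for f in flags] == [FlagType.MALFORMED_ACCESSION]

    def test_unknown_symbol_flagged(self, bundle, index):
        flags = audit_interactions(
            [rec("genesymbol:NOPE9", "uniprotkb:P07911")],
            index, bundle.proteins,
        )
        assert [f.flag for f in flags] == [FlagType.UNKNOWN_SYMBOL]

    def test_auditing_is_order_independent(self, bundle, index):
        records = [
            rec("genesymbol:CK", "uniprotkb:P35790", line=1),
            rec("uniprotkb:Q540J6", "genesymbol:CHKA", line=2),
            rec("uniprotkb:P07911", "uniprotkb:P35790", line=3),
        ]
        def signature(flags):
            return sorted(
                (f.record.raw_line_no, f.participant, f.flag.value)
                for f in flags
            )
        base = signature(audit_interactions(records, index, bundle.proteins))
        for perm in itertools.permutations(records):
            assert signature(
                audit_interactions(list(perm), index, bundle.proteins)
            ) == base


class TestMerge:
    def test_same_pair_from_two_sources_collapses(self, bundle, index):
        merged = merge_sources(
            [
                [rec("uniprotkb:P35790", "uniprotkb:P07911", source="dbA")],
                [rec("uniprotkb:P35790", "uniprotkb:P07911", source="dbB",
                     pub="pub:2")],
            ],
            index=index, proteins=bundle.proteins,
        )
        assert len(merged) == 1
        assert len(merged[0].provenance) == 2

    def test_unordered_pair_symmetry(self, bundle, index):
        merged = merge_sources(
            [
                [rec("uniprotkb:P35790", "uniprotkb:P07911", source="dbA")],
                [rec("uniprotkb:P07911", "uniprotkb:P35790", source="dbB")],
            ],
            index=index, proteins=bundle.proteins,
        )
        assert len(merged) == 1

    def test_secondary_accessions_canonicalised_before_merging(
        self, bundle, index
    ):
        merged = merge_sources(
            [
                [rec("uniprotkb:Q540J6", "uniprotkb:P35790", source="dbA")],
                [rec("uniprotkb:P07911", "uniprotkb:P35790", source="dbB")],
            ],
            index=index, proteins=bundle.proteins,
        )
        assert len(merged) == 1
        values = {merged[0].id_a.value, merged[0].id_b.value}
        assert values == {"P07911", "P35790"}

    def test_unambiguous_symbol_promoted_to_accession(self, bundle, index):
        merged = merge_sources(
            [
                [rec("genesymbol:CHKA", "uniprotkb:P07911", source="dbA")],
                [rec("uniprotkb:P35790", "uniprotkb:P07911", source="dbB")],
            ],
            index=index, proteins=bundle.proteins,
        )
        assert len(merged) == 1

    def test_ambiguous_symbols_never_merge_across_sources(
        self, bundle, index
    ):
        merged = merge_sources(
            [
                [rec("genesymbol:CK", "uniprotkb:P07911", source="dbA")],
                [rec("genesymbol:CK", "uniprotkb:P07911", source="dbB")],
            ],
            index=index, proteins=bundle.proteins,
        )
        assert len(merged) == 2
        assert not any(m.fully_resolved for m in merged)

    def test_inclusion_exclusion_oracle(self, bundle, index):
        """Merged size equals the brute-force count of distinct unordered
        canonical pairs planted across three sources."""
        rng = random.Random(42)
        accessions = [r.primary_accession for r in bundle.proteins]
        pool = [tuple(sorted(rng.sample(accessions, 2))) for _ in range(12)]
        lists = []
        for source in ("dbA", "dbB", "dbC"):
            pairs = rng.sample(pool, k=rng.randint(4, 10))
            lists.append(
                [rec(f"uniprotkb:{a}", f"uniprotkb:{b}", source=source)
                 for a, b in pairs]
            )
        expected = len(
            {tuple(sorted((str(r.id_a), str(r.id_b))))
             for lst in lists for r in lst}
        )
        merged = merge_sources(lists, index=index, proteins=bundle.proteins)
        assert len(merged) == expected

    def test_merge_is_idempotent(self, bundle, index):
        lists = [
            [rec("uniprotkb:P35790", "uniprotkb:P07911", source="dbA"),
             rec("genesymbol:CK", "uniprotkb:P07911", source="dbA")],
            [rec("uniprotkb:P07911", "uniprotkb:P35790", source="dbB")],
        ]
        once = merge_sources(lists, index=index, proteins=bundle.proteins)
        twice = merge_sources([once], index=index, proteins=bundle.proteins)
        assert [(m.id_a, m.id_b, m.provenance) for m in once] == [
            (m.id_a, m.id_b, m.provenance) for m in twice
        ]

    def test_merge_commutes_over_input_order(self, bundle, index):
        lists = [
            [rec("uniprotkb:P35790", "uniprotkb:P07911", source="dbA")],
            [rec("uniprotkb:P07911", "uniprotkb:P35790", source="dbB")],
            [rec("genesymbol:CHKA", "uniprotkb:P18754", source="dbC")],
        ]
        def shape(merged):
            return sorted(
                (str(m.id_a), str(m.id_b), frozenset(m.provenance))
                for m in merged
            )
        base = shape(merge_sources(lists, index=index,
                                   proteins=bundle.proteins))
        for perm in itertools.permutations(lists):
            assert shape(
                merge_sources(list(perm), index=index,
                              proteins=bundle.proteins)
            ) == base

    def test_requires_at_least_one_list(self):
        with pytest.raises(ValueError):
            merge_sources([])


class TestCurate:
    def test_dream_psen1_supported(self, bundle, index):
        merged = merge_sources(
            [[rec("uniprotkb:Q9Y2W7", "uniprotkb:P49768")]],
            index=index, proteins=bundle.proteins,
        )
        (result,) = curate(merged, bundle.curated)
        assert result.category is Category.SUPPORTED
        assert result.matched_partner == "PSEN1"

    def test_rcc1_rejected_against_chka_reference(self, bundle, index):
        """A choline-kinase interaction list naming RCC1 is rejected when
        the reference carries RCC1 as a curated false positive."""
        reference = CuratedInteractome(
            query_protein=bundle.proteins.by_primary("P35790"),
            entries=[
                CuratedEntry(
                    partner_symbol="RCC1",
                    partner_accession="P18754",
                    year=2013,
                    reference="db:STRING-9.0",
                    notes="retrieval artefact, no experimental evidence",
                    status="rejected",
                )
            ],
        )
        merged = merge_sources(
            [[rec("uniprotkb:P35790", "uniprotkb:P18754")]],
            index=index, proteins=bundle.proteins,
        )
        (result,) = curate(merged, reference)
        assert result.category is Category.REJECTED

    def test_novel_partner_unverified(self, bundle, index):
        merged = merge_sources(
            [[rec("uniprotkb:Q9Y2W7", "uniprotkb:P35790")]],
            index=index, proteins=bundle.proteins,
        )
        (result,) = curate(merged, bundle.curated)
        assert result.category is Category.UNVERIFIED

    def test_record_without_query_protein_out_of_scope(self, bundle, index):
        merged = merge_sources(
            [[rec("uniprotkb:P35790", "uniprotkb:P07911")]],
            index=index, proteins=bundle.proteins,
        )
        (result,) = curate(merged, bundle.curated)
        assert result.category is Category.OUT_OF_SCOPE

    def test_self_interaction_supported_via_query_row(self, bundle, index):
        merged = merge_sources(
            [[rec("uniprotkb:Q9Y2W7", "uniprotkb:Q9Y2W7")]],
            index=index, proteins=bundle.proteins,
        )
        (result,) = curate(merged, bundle.curated)
        assert result.category is Category.SUPPORTED
        assert result.matched_partner == "KCNIP3"

    def test_symbol_only_match_flagged_lower_confidence(self, bundle, index):
        merged = merge_sources(
            [[rec("uniprotkb:Q9Y2W7", "genesymbol:CSNK1D")]],
            index=index, proteins=bundle.proteins,
        )
        (result,) = curate(merged, bundle.curated)
        assert result.category is Category.REJECTED
        assert result.via_symbol

    def test_every_record_gets_exactly_one_category(self, bundle, index):
        records = read_mitab(bundle.mitab_path)
        extra = [
            rec("genesymbol:CK", "uniprotkb:Q9Y2W7", source="dbX"),
            rec("uniprotkb:P35790", "uniprotkb:P07911", source="dbX"),
        ]
        merged = merge_sources([records, extra], index=index,
                               proteins=bundle.proteins)
        results = curate(merged, bundle.curated)
        assert len(results) == len(merged)
        assert all(isinstance(r.category, Category) for r in results)

    def test_unresolvable_query_protein_is_error(self, bundle, index):
        bad_query = ProteinRecord("P00000", (), "XXXX_HUMAN")
        reference = CuratedInteractome(query_protein=bad_query, entries=[])
        object.__setattr__(bad_query, "primary_accession", "notanacc")
        with pytest.raises(CurationError):
            curate([], reference)


class TestWriteReport:
    def test_empty_flag_list_yields_header_only_tsv(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report([], path, fmt="tsv")
        lines = path.read_text().splitlines()
        assert lines == ["\t".join(AuditFlag.COLUMNS)]

    def test_two_flags_two_rows(self, bundle, index, tmp_path):
        flags = audit_interactions(
            [rec("genesymbol:CK", "genesymbol:NOPE9")],
            index, bundle.proteins,
        )
        assert len(flags) == 2
        path = tmp_path / "r.tsv"
        write_report(flags, path)
        assert len(path.read_text().splitlines()) == 3

    def test_json_round_trip(self, bundle, index, tmp_path):
        flags = audit_interactions(
            [rec("genesymbol:CK", "uniprotkb:Q540J6")],
            index, bundle.proteins,
        )
        path = tmp_path / "r.json"
        write_report(flags, path, fmt="json")
        assert json.loads(path.read_text()) == [f.as_row() for f in flags]
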