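"""Metabolite XML parsing, kingdom partitioning and biofluid Venn regions."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings, strategies as st
from lxml import etree

from mminet.hmdb import (
    Biofluid,
    Kingdom,
    MetaboliteRecord,
    biofluid_overlap,
    merge_biofluid_collections,
    normalize_taxon,
    parse_metabolite_xml,
    partition_by_kingdom,
)
from mminet.synthetic import write_hmdb_dialect_xml

from conftest import make_record


def _parse_string(xml: str) -> list[MetaboliteRecord]:
    return parse_metabolite_xml(io.BytesIO(xml.encode()))


XML_TEMPLATE = """<metabolites>{body}</metabolites>"""


def _metabolite_xml(accession, biofluids, sources) -> str:
    fluid_xml = "".join(f"<biospecimen>{f}</biospecimen>" for f in biofluids)
    source_xml = "".join(
        f'<source kingdom="{k}">{t}</source>' if t else f'<source kingdom="{k}"/>'
        for k, t in sources
    )
    return (
        f"<metabolite><accession>{accession}</accession><name>x</name>"
        f"<biospecimen_locations>{fluid_xml}</biospecimen_locations>"
        f"<biological_disposition>{source_xml}</biological_disposition></metabolite>"
    )


class TestParse:
    def test_bacteria_only_without_names_is_retained(self):
        xml = XML_TEMPLATE.format(
            body=_metabolite_xml("M1", ["Feces"], [("Bacteria", None)])
        )
        records = _parse_string(xml)
        assert len(records) == 1
        rec = records[0]
        assert rec.kingdoms == {Kingdom.BACTERIA}
        assert rec.source_taxa == frozenset()
        assert rec.biofluids == {Biofluid.FECES}

    def test_non_microbial_disposition_is_excluded(self):
        xml = XML_TEMPLATE.format(
            body=_metabolite_xml("M1", ["Feces"], [("Plant", "Arabidopsis")])
        )
        assert _parse_string(xml) == []

    def test_kingdom_matching_is_case_insensitive(self):
        xml = XML_TEMPLATE.format(
            body=_metabolite_xml("M1", ["Serum"], [("bacteria", "E coli")])
        )
        records = _parse_string(xml)
        assert records[0].kingdoms == {Kingdom.BACTERIA}

    def test_unknown_biofluid_label_ignored_with_warning(self, caplog):
        xml = XML_TEMPLATE.format(
            body=_metabolite_xml("M1", ["Urine", "Feces"], [("Bacteria", None)])
        )
        with caplog.at_level("WARNING"):
            records = _parse_string(xml)
        assert records[0].biofluids == {Biofluid.FECES}
        assert any("Urine" in msg for msg in caplog.messages)

    def test_malformed_xml_raises_with_line_context(self):
        with pytest.raises(etree.XMLSyntaxError):
            _parse_string("<metabolites><metabolite></metabolites>")

    def test_hand_labelled_kingdom_fixture(self):
        """6 bacteria-only, 2 fungi-only, 2 both: all retained with exact sets."""
        body = []
        expected = []
        for i in range(6):
            body.append(_metabolite_xml(f"B{i}", ["Feces"], [("Bacteria", None)]))
            expected.append({Kingdom.BACTERIA})
        for i in range(2):
            body.append(_metabolite_xml(f"F{i}", ["Feces"], [("Fungi", None)]))
            expected.append({Kingdom.FUNGI})
        for i in range(2):
            body.append(
                _metabolite_xml(
                    f"X{i}", ["Feces"], [("Bacteria", None), ("Fungi", None)]
                )
            )
            expected.append({Kingdom.BACTERIA, Kingdom.FUNGI})
        records = _parse_string(XML_TEMPLATE.format(body="".join(body)))
        assert len(records) == 10
        assert [set(r.kingdoms) for r in records] == expected


class TestNormalizeTaxon:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  escherichia   coli ", "Escherichia coli"),
            ("lactobacillus", "Lactobacillus"),
            ("Bacillus subtilis", "Bacillus subtilis"),
        ],
    )
    def test_whitespace_and_capitalization(self, raw, expected):
        assert normalize_taxon(raw) == expected


class TestMerge:
    def test_same_id_unions_biofluids(self):
        a = make_record("M1", biofluids=[Biofluid.FECES])
        b = make_record("M1", biofluids=[Biofluid.SERUM])
        merged = merge_biofluid_collections([a], [b], [])
        assert len(merged) == 1
        assert merged[0].biofluids == {Biofluid.FECES, Biofluid.SERUM}

    def test_disjoint_ids_concatenate(self):
        feces = [make_record(f"F{i}") for i in range(2)]
        serum = [make_record(f"S{i}") for i in range(3)]
        csf = [make_record(f"C{i}") for i in range(4)]
        assert len(merge_biofluid_collections(feces, serum, csf)) == 9

    def test_overlapping_fixture_union_of_seven(self):
        feces = [make_record(m) for m in ("M1", "M2", "M3", "M4")]
        serum = [make_record(m) for m in ("M3", "M4", "M5", "M6")]
        csf = [make_record(m) for m in ("M6", "M7")]
        merged = merge_biofluid_collections(feces, serum, csf)
        assert {r.metabolite_id for r in merged} == {f"M{i}" for i in range(1, 8)}


class TestKingdomPartition:
    def test_empty_input(self):
        part = partition_by_kingdom([])
        assert (part.bacteria_only, part.fungi_only, part.both, part.total) == (0, 0, 0, 0)

    def test_matches_per_record_classification_oracle(self, default_bundle):
        records = default_bundle.records
        part = partition_by_kingdom(records)
        b = sum(1 for r in records if r.kingdoms == {Kingdom.BACTERIA})
        f = sum(1 for r in records if r.kingdoms == {Kingdom.FUNGI})
        both = sum(1 for r in records if len(r.kingdoms) == 2)
        assert (part.bacteria_only, part.fungi_only, part.both) == (b, f, both)
        assert part.total == len(records)


class TestBiofluidOverlap:
    def test_all_records_in_all_fluids(self):
        records = [
            make_record(f"M{i}", biofluids=list(Biofluid)) for i in range(5)
        ]
        overlap = biofluid_overlap(records)
        assert overlap.all_three == 5
        assert overlap.total == 5

    def test_pairwise_disjoint_fluids(self):
        records = [
            make_record("M1", biofluids=[Biofluid.FECES]),
            make_record("M2", biofluids=[Biofluid.SERUM]),
            make_record("M3", biofluids=[Biofluid.CSF]),
        ]
        overlap = biofluid_overlap(records)
        assert (overlap.feces_only, overlap.serum_only, overlap.csf_only) == (1, 1, 1)
        assert overlap.feces_serum == overlap.all_three == 0

    def test_known_venn_fixture(self):
        F, S, C = Biofluid.FECES, Biofluid.SERUM, Biofluid.CSF
        memberships = [(F,), (F, S), (F, S), (F, S, C), (S, C), (C,), (C,)]
        records = [
            make_record(f"M{i}", biofluids=fluids)
            for i, fluids in enumerate(memberships)
        ]
        overlap = biofluid_overlap(records)
        assert overlap.feces_only == 1
        assert overlap.feces_serum == 2
        assert overlap.all_three == 1
        assert overlap.serum_csf == 1
        assert overlap.csf_only == 2
        assert overlap.total == 7

    def test_unknown_kingdom_filter_raises(self):
        with pytest.raises(ValueError, match="unknown kingdom"):
            biofluid_overlap([make_record("M1")], "ARCHAEA")

    def test_kingdom_filters_cover_all_records(self, default_bundle):
        """Bacteria- and fungi-filtered totals cover every retained record."""
        records = default_bundle.records
        bact = biofluid_overlap(records, Kingdom.BACTERIA)
        fung = biofluid_overlap(records, Kingdom.FUNGI)
        both = partition_by_kingdom(records).both
        assert bact.total + fung.total - both == len(records)


record_strategy = st.builds(
    make_record,
    metabolite_id=st.text(
        alphabet=st.characters(whitelist_categories=["Lu", "Nd"]), min_size=1, max_size=8
    ),
    biofluids=st.sets(st.sampled_from(list(Biofluid)), min_size=1).map(tuple),
    kingdoms=st.sets(st.sampled_from(list(Kingdom)), min_size=1).map(tuple),
    source_taxa=st.sets(
        st.sampled_from(["Escherichia coli", "Lactobacillus", "Candida albicans"])
    ).map(tuple),
)


@settings(max_examples=30, derandomize=True)
@given(records=st.lists(record_strategy, min_size=1, max_size=20, unique_by=lambda r: r.metabolite_id))
def test_xml_round_trip_preserves_records(tmp_path_factory, records):
    """Writing then parsing the dialect reproduces every record field."""
    path = tmp_path_factory.mktemp("xml") / "roundtrip.xml"
    write_hmdb_dialect_xml(records, path)
    parsed = parse_metabolite_xml(str(path))
    assert {r.metabolite_id: r for r in parsed} == {r.metabolite_id: r for r in records}


def test_parser_idempotence(default_bundle, tmp_path):
    """parse(write(parse(x))) == parse(x) on generated records."""
    first = default_bundle.records
    path = tmp_path / "again.xml"
    write_hmdb_dialect_xml(first, path)
    second = parse_metabolite_xml(str(path))
    assert {r.metabolite_id: r for r in second} == {r.metabolite_id: r for r in first}
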