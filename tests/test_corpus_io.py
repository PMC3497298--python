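"""Readers, writers, validation and round-trip contracts."""

from datetime import date

import pytest

from pdbtriage import (
    ValidationError,
    read_annotations,
    read_sequence_hits,
    read_structure_entries,
    read_structure_hits,
    write_annotations,
    write_sequence_hits,
    write_structure_entries,
    write_structure_hits,
)
from pdbtriage.corpus_io import TriageError

from helpers import make_annotation

ENTRY_HEADER = "pdb_id\tmolecule_name\tclassification_header\tdeposition_date\tspecies\taccessions\n"
ANN_HEADER = (
    "accession\tprotein_name\treviewed\tfunction_text\tcatalytic_activity"
    "\tec_numbers\tgo_terms\tintegration_date\n"
)
STRUCT_HEADER = (
    "query_id\tsubject_pdb_id\tz_score\trmsd_angstrom\tsubject_classification"
    "\tsubject_name\tsubject_deposition_date\n"
)


def _entry_row(pdb_id, acc=""):
    return f"{pdb_id}\thypothetical protein\tunknown function\t2003-01-15\tBacillus subtilis\t{acc}\n"


class TestStructureEntries:
    def test_entries_returned_in_file_order(self, tmp_path):
        p = tmp_path / "entries.tsv"
        p.write_text(ENTRY_HEADER + _entry_row("1htw") + _entry_row("1jzt") + _entry_row("1l0b"))
        entries = read_structure_entries(p)
        assert [e.pdb_id for e in entries] == ["1htw", "1jzt", "1l0b"]
        assert entries[0].deposition_date == date(2003, 1, 15)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "entries.tsv"
        p.write_text(ENTRY_HEADER)
        assert read_structure_entries(p) == []

    def test_malformed_id_reported_with_line_number(self, tmp_path):
        p = tmp_path / "entries.tsv"
        p.write_text(ENTRY_HEADER + _entry_row("XY"))
        with pytest.raises(ValidationError, match=r"entries\.tsv:2"):
            read_structure_entries(p)

    def test_duplicate_pdb_id_listed(self, tmp_path):
        p = tmp_path / "entries.tsv"
        p.write_text(ENTRY_HEADER + _entry_row("1htw") + _entry_row("1htw"))
        with pytest.raises(ValidationError, match="duplicate pdb_id '1htw'"):
            read_structure_entries(p)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(TriageError, match="not found"):
            read_structure_entries(tmp_path / "nope.tsv")


class TestAnnotations:
    def test_record_keyed_by_accession_with_date(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            ANN_HEADER
            + "Q66624\tThymidine kinase\ttrue\t\t\t2.7.1.21\t"
            "GO:0016301|MOLECULAR_FUNCTION|kinase activity\t2011-03-08\n"
        )
        records = read_annotations(p)
        assert records["Q66624"].integration_date == date(2011, 3, 8)
        assert records["Q66624"].go_terms[0].term_name == "kinase activity"

    def test_empty_annotation_fields_are_valid(self, tmp_path):
        # sufficiency is decided downstream, not at parse time
        p = tmp_path / "ann.tsv"
        p.write_text(ANN_HEADER + "P11111\tSome protein\tfalse\t\t\t\t\t2004-02-02\n")
        rec = read_annotations(p)["P11111"]
        assert rec.go_terms == () and rec.function_text == ""

    def test_unknown_go_domain_token_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            ANN_HEADER + "P1\tX\ttrue\t\t\t\tGO:0000001|MF|kinase activity\t2004-02-02\n"
        )
        with pytest.raises(ValidationError, match="unknown GO domain token 'MF'"):
            read_annotations(p)

    def test_malformed_ec_number_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(ANN_HEADER + "P1\tX\ttrue\t\t\tabc\t\t2004-02-02\n")
        with pytest.raises(ValidationError, match="EC number"):
            read_annotations(p)


def _blast_row(q="1htw", s="P00001", pident="45.00"):
    return f"{q}\t{s}\t{pident}\t200\t90\t1\t1\t200\t1\t200\t1.00e-30\t150.0\n"


class TestSequenceHits:
    def _annotations(self):
        return {f"P0000{i}": make_annotation(accession=f"P0000{i}") for i in range(1, 6)}

    def test_hits_grouped_and_enriched(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_row() + _blast_row(s="P00002") + _blast_row(s="P00003"))
        grouped = read_sequence_hits(p, self._annotations())
        assert len(grouped["1htw"]) == 3
        assert grouped["1htw"][0].subject_name == "Thymidine kinase"
        assert grouped.get("9zzz", []) == []

    def test_chain_suffix_stripped_for_grouping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_row(q="1htw_A") + _blast_row(q="1htw", s="P00002"))
        grouped = read_sequence_hits(p, self._annotations())
        assert len(grouped["1htw"]) == 2
        assert grouped["1htw"][0].query_id == "1htw_A"  # raw id retained

    def test_identity_above_100_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_row(pident="101.0"))
        with pytest.raises(ValidationError, match="percent identity 101.0"):
            read_sequence_hits(p, self._annotations())

    def test_file_order_matches_resort_oracle(self, tmp_path):
        # ten rows written in descending bit-score order must come back as-is
        rows = [
            f"1htw\tP0000{1 + i % 5}\t{40 + i}.00\t200\t90\t1\t1\t200\t1\t200"
            f"\t1.00e-30\t{400 - 10 * i}.0\n"
            for i in range(10)
        ]
        p = tmp_path / "hits.tsv"
        p.write_text("".join(rows))
        hits = read_sequence_hits(p, self._annotations())["1htw"]
        assert [h.bit_score for h in hits] == sorted(
            (h.bit_score for h in hits), reverse=True
        )
        assert [h.percent_identity for h in hits] == [40.0 + i for i in range(10)]

    def test_missing_subject_lenient_excludes_strict_raises(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_row() + _blast_row(s="P99999"))
        grouped = read_sequence_hits(p, self._annotations(), strict=False)
        assert len(grouped["1htw"]) == 1
        with pytest.raises(ValidationError, match="P99999"):
            read_sequence_hits(p, self._annotations(), strict=True)

    def test_strict_grouping_conserves_row_count(self, small_corpus):
        annotations = read_annotations(small_corpus.paths["annotations"])
        grouped = read_sequence_hits(
            small_corpus.paths["sequence_hits"], annotations, strict=True
        )
        n_rows = len(
            small_corpus.paths["sequence_hits"].read_text().splitlines()
        )
        assert sum(len(v) for v in grouped.values()) == n_rows


class TestStructureHits:
    def test_z_score_and_date_parsed(self, tmp_path):
        p = tmp_path / "shits.tsv"
        p.write_text(
            STRUCT_HEADER
            + "3hfq\t1jof\t39.5\t1.8\tisomerase\tCarboxymuconate cyclase\t2011-04-28\n"
        )
        grouped = read_structure_hits(p)
        hit = grouped["3hfq"][0]
        assert hit.z_score == 39.5
        assert hit.subject_deposition_date == date(2011, 4, 28)

    def test_header_only_file_gives_empty_mapping(self, tmp_path):
        p = tmp_path / "shits.tsv"
        p.write_text(STRUCT_HEADER)
        assert read_structure_hits(p) == {}

    def test_negative_rmsd_rejected(self, tmp_path):
        p = tmp_path / "shits.tsv"
        p.write_text(
            STRUCT_HEADER + "3hfq\t1jof\t39.5\t-1.0\tisomerase\tX\t2011-04-28\n"
        )
        with pytest.raises(ValidationError, match="negative RMSD"):
            read_structure_hits(p)


class TestRoundTrips:
    def test_write_read_is_byte_identical_for_all_four_files(
        self, small_corpus, tmp_path
    ):
        paths = small_corpus.paths
        annotations = read_annotations(paths["annotations"])
        write_structure_entries(
            read_structure_entries(paths["entries"]), tmp_path / "e.tsv"
        )
        write_annotations(annotations, tmp_path / "a.tsv")
        write_sequence_hits(
            read_sequence_hits(paths["sequence_hits"], annotations, strict=True),
            tmp_path / "s.tsv",
        )
        write_structure_hits(
            read_structure_hits(paths["structure_hits"]), tmp_path / "h.tsv"
        )
        for src, dst in [
            (paths["entries"], "e.tsv"),
            (paths["annotations"], "a.tsv"),
            (paths["sequence_hits"], "s.tsv"),
            (paths["structure_hits"], "h.tsv"),
        ]:
            assert (tmp_path / dst).read_bytes() == src.read_bytes()
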