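"""Curation-template parsing and row-to-phenopacket conversion."""

import csv

import pytest

from phenocurate.errors import CellError, FormatError
from phenocurate.ingest import (
    FIXED_COLUMNS,
    IngestOptions,
    ingest,
    read_template,
    row_to_phenopacket,
)
from phenocurate.model import Sex
from phenocurate.ontology import OntologyGraph, OntologyTerm
from phenocurate.model import TermId
from phenocurate.pjson import read_corpus

TERMS = [("Seizure", "HP:9000002"), ("Ataxia", "HP:9000003"), ("Scoliosis", "HP:9000004")]

FIXED_MARKERS = {
    "PMID": "str", "title": "str", "individual_id": "str", "disease_id": "str",
    "disease_label": "str", "hgnc_id": "str", "gene_symbol": "str",
    "transcript": "optional", "allele_1": "str", "allele_2": "optional",
    "age_of_onset": "age", "age_at_last_encounter": "age",
    "deceased": "optional", "sex": "str",
}


def base_row(**overrides) -> dict:
    row = {
        "PMID": "90000001", "title": "A synthetic case report",
        "individual_id": "patient 1", "disease_id": "OMIM:900001",
        "disease_label": "Synthetic disease", "hgnc_id": "HGNC:90000",
        "gene_symbol": "GENE1", "transcript": "NM_90000.1",
        "allele_1": "c.100A>G", "allele_2": "", "age_of_onset": "P1Y",
        "age_at_last_encounter": "P10Y", "deceased": "no", "sex": "F",
        "HP:9000002": "observed", "HP:9000003": "excluded", "HP:9000004": "na",
    }
    row.update(overrides)
    return row


def write_template(path, rows, term_cols=TERMS, drop_fixed=(), dup_curie=False):
    fixed = [c for c in FIXED_COLUMNS if c not in drop_fixed]
    header1 = fixed + [label for label, _ in term_cols]
    header2 = [FIXED_MARKERS[c] for c in fixed] + [cur for _, cur in term_cols]
    if dup_curie:
        header1.append(term_cols[0][0])
        header2.append(term_cols[0][1])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header1)
        w.writerow(header2)
        for row in rows:
            w.writerow(
                [row.get(c, "") for c in fixed]
                + [row.get(cur, "na") for _, cur in term_cols]
                + ([row.get(term_cols[0][1], "na")] if dup_curie else [])
            )
    return path


@pytest.fixture
def toy_ontology() -> OntologyGraph:
    terms = {
        TermId("HP:9000001"): OntologyTerm(TermId("HP:9000001"), "root"),
        TermId("HP:9000002"): OntologyTerm(
            TermId("HP:9000002"), "Seizure", parents={TermId("HP:9000001")}
        ),
        TermId("HP:9000003"): OntologyTerm(
            TermId("HP:9000003"), "Ataxia", parents={TermId("HP:9000001")}
        ),
        TermId("HP:9000004"): OntologyTerm(
            TermId("HP:9000004"), "Scoliosis", parents={TermId("HP:9000001")}
        ),
    }
    return OntologyGraph(terms, TermId("HP:9000001"))


class TestReadTemplate:
    def test_toy_template_shape(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row(), base_row(individual_id="p2")])
        table = read_template(path)
        assert len(table.term_columns) == 3
        assert table.n_rows == 2
        assert table.term_columns[0] == ("Seizure", "HP:9000002")

    def test_missing_fixed_column_names_it(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row()], drop_fixed=("PMID",))
        with pytest.raises(FormatError, match="PMID"):
            read_template(path)

    def test_duplicate_term_curie_rejected(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row()], dup_curie=True)
        with pytest.raises(FormatError, match="twice"):
            read_template(path)

    def test_tsv_and_xlsx_dialects(self, tmp_path):
        import openpyxl

        csv_path = write_template(tmp_path / "t.csv", [base_row()])
        table = read_template(csv_path)
        # same content through xlsx
        wb = openpyxl.Workbook()
        ws = wb.active
        with open(csv_path) as fh:
            for row in csv.reader(fh):
                ws.append(row)
        xlsx_path = tmp_path / "t.xlsx"
        wb.save(xlsx_path)
        table2 = read_template(xlsx_path)
        assert table2.term_columns == table.term_columns
        assert table2.rows == table.rows


class TestRowConversion:
    def test_cell_vocabulary(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row(**{"HP:9000004": "P2Y"})])
        p = row_to_phenopacket(read_template(path), 0)
        by_id = {str(f.type.id): f for f in p.phenotypic_features}
        assert not by_id["HP:9000002"].excluded and by_id["HP:9000002"].onset is None
        assert by_id["HP:9000003"].excluded
        assert by_id["HP:9000004"].onset.iso8601 == "P2Y"
        assert not by_id["HP:9000004"].excluded

    def test_na_cells_emit_no_feature(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row()])
        p = row_to_phenopacket(read_template(path), 0)
        assert len(p.phenotypic_features) == 2  # HP:9000004 is na

    def test_id_and_subject_fields(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row()])
        p = row_to_phenopacket(read_template(path), 0)
        assert p.id == "PMID_90000001_patient_1"
        assert p.subject.sex is Sex.FEMALE
        assert p.subject.time_at_last_encounter.iso8601 == "P10Y"
        assert p.diseases[0].onset.iso8601 == "P1Y"

    def test_homozygous_single_descriptor(self, tmp_path):
        hgvs = "NM_90000.1:c.59G>A"
        path = write_template(tmp_path / "t.csv", [base_row(allele_1=hgvs, allele_2=hgvs)])
        p = row_to_phenopacket(read_template(path), 0)
        descs = p.interpretations[0].genomic_interpretations
        assert len(descs) == 1
        assert descs[0].descriptor.allelic_state.label == "homozygous"
        assert descs[0].descriptor.expressions[0].value == hgvs

    def test_distinct_alleles_two_heterozygous(self, tmp_path):
        path = write_template(
            tmp_path / "t.csv", [base_row(allele_1="c.100A>G", allele_2="c.200C>T")]
        )
        p = row_to_phenopacket(read_template(path), 0)
        descs = p.interpretations[0].genomic_interpretations
        assert len(descs) == 2
        assert {d.descriptor.allelic_state.label for d in descs} == {"heterozygous"}
        # bare c. alleles get the transcript prefix
        assert descs[0].descriptor.expressions[0].value == "NM_90000.1:c.100A>G"

    def test_single_allele_hemizygous_option(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row(allele_2="")])
        table = read_template(path)
        het = row_to_phenopacket(table, 0)
        hemi = row_to_phenopacket(table, 0, IngestOptions(hemizygous=True))
        state = lambda p: p.interpretations[0].genomic_interpretations[0].descriptor.allelic_state.label  # noqa: E731
        assert state(het) == "heterozygous"
        assert state(hemi) == "hemizygous"

    def test_qualitative_sv_allele(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row(allele_1="gene deletion")])
        p = row_to_phenopacket(read_template(path), 0)
        d = p.interpretations[0].genomic_interpretations[0].descriptor
        assert d.sv_label == "gene deletion"
        assert d.expressions == []

    def test_bad_age_cell_has_coordinates(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row(**{"HP:9000004": "4y"})])
        with pytest.raises(CellError) as err:
            row_to_phenopacket(read_template(path), 0)
        assert err.value.row == 0 and err.value.column == "HP:9000004"

    def test_bad_sex_cell_errors(self, tmp_path):
        path = write_template(tmp_path / "t.csv", [base_row(sex="both")])
        with pytest.raises(CellError):
            row_to_phenopacket(read_template(path), 0)


class TestIngest:
    def test_clean_template_writes_all_rows(self, tmp_path, toy_ontology):
        rows = [base_row(individual_id=f"p{i}") for i in range(5)]
        path = write_template(tmp_path / "t.csv", rows)
        result = ingest(read_template(path), toy_ontology, tmp_path / "corpus")
        assert result.written == 5
        assert result.issues == []
        assert read_corpus(tmp_path / "corpus").n_ok == 5

    def test_faulty_rows_held_back(self, tmp_path, toy_ontology):
        rows = [base_row(individual_id=f"p{i}") for i in range(5)]
        rows[2]["HP:9000002"] = "observed"
        rows[2]["individual_id"] = "p1"  # duplicate (PMID, individual) pair
        path = write_template(tmp_path / "t.csv", rows)
        result = ingest(read_template(path), toy_ontology, tmp_path / "corpus")
        # the duplicated row collides on both the packet id and the
        # (PMID, individual) pair; both copies share the id, so both are
        # held back (writing both would silently overwrite one file)
        assert result.written == 3
        assert {i.rule_id for i in result.issues} == {"C1", "C2"}

    def test_unknown_term_row_held_back(self, tmp_path, toy_ontology):
        rows = [base_row(individual_id=f"p{i}") for i in range(3)]
        path = write_template(
            tmp_path / "t.csv", rows,
            term_cols=TERMS + [("Mystery", "HP:8888888")],
        )
        # make one row assert the unknown term
        table = read_template(path)
        table.rows[1]["HP:8888888"] = "observed"
        result = ingest(table, toy_ontology, tmp_path / "corpus")
        assert result.written == 2
        assert [i.rule_id for i in result.issues] == ["R3"]

    def test_pipeline_matches_direct_row_construction(self, tmp_path, toy_ontology):
        rows = [base_row(individual_id=f"p{i}") for i in range(5)]
        path = write_template(tmp_path / "t.csv", rows)
        table = read_template(path)
        ingest(table, toy_ontology, tmp_path / "corpus")
        loaded = read_corpus(tmp_path / "corpus")
        direct = {p.id: p for p in (row_to_phenopacket(table, i) for i in range(5))}
        assert len(loaded.phenopackets) == 5
        for p in loaded.phenopackets:
            assert p == direct[p.id]
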