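"""Convert a tabular curation template into phenopackets.

Case-report supplements usually tabulate patients in rows with one column
per data item. The template dialect read here makes that machine-checkable:

* two header rows — row 1 carries column labels, row 2 carries the HPO CURIE
  for phenotype columns and a ``str``/``age``/``optional`` marker for the
  fixed metadata columns;
* fixed columns: PMID, title, individual_id, disease_id, disease_label,
  hgnc_id, gene_symbol, transcript, allele_1, allele_2, age_of_onset,
  age_at_last_encounter, deceased, sex;
* phenotype cells hold ``observed``, ``excluded``, ``na`` (or blank), or an
  ISO 8601 age — the age form asserts the feature present with that onset.

Anything else in a cell is an error with (row, column) coordinates;
curation safety beats convenience. Alleles are given as HGVS strings
(``NM_...:c.59G>A``, or bare ``c.59G>A`` completed with the transcript
column); text with no HGVS anchor is kept verbatim as a qualitative
structural-variant label. Equal alleles make one homozygous descriptor,
distinct alleles two heterozygous ones, a single allele one heterozygous
(or hemizygous) descriptor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import CellError, FormatError
from .model import (
    AgeValue,
    DiseaseDx,
    Expression,
    GeneContext,
    GenomicInterpretation,
    HgvsSyntax,
    Individual,
    Interpretation,
    InterpretationStatus,
    MetaDataBlock,
    OntologyClass,
    ParseError,
    Phenopacket,
    PhenotypicFeature,
    Sex,
    TermId,
    VariationDescriptor,
    HPO_PATTERN,
    make_phenopacket_id,
    parse_age,
)
from .ontology import OntologyGraph
from .resources import resources_for
from .validate import Level, RuleConfig, ValidationIssue, validate_corpus

__all__ = [
    "FIXED_COLUMNS",
    "CurationTable",
    "IngestOptions",
    "IngestResult",
    "read_template",
    "row_to_phenopacket",
    "ingest",
]

FIXED_COLUMNS = (
    "PMID",
    "title",
    "individual_id",
    "disease_id",
    "disease_label",
    "hgnc_id",
    "gene_symbol",
    "transcript",
    "allele_1",
    "allele_2",
    "age_of_onset",
    "age_at_last_encounter",
    "deceased",
    "sex",
)

_SEX_MAP = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "o": Sex.OTHER_SEX,
    "other": Sex.OTHER_SEX,
    "u": Sex.UNKNOWN_SEX,
    "unknown": Sex.UNKNOWN_SEX,
    "": Sex.UNKNOWN_SEX,
}

_HGVS_ANCHOR = re.compile(r":([cgp])\.")


@dataclass
class CurationTable:
    """Parsed template: fixed metadata columns plus per-HPO-term columns."""

    fixed_index: dict[str, int]
    term_columns: list[tuple[str, TermId]]  # (label, curie) in column order
    rows: list[dict[str, str]]  # fixed values by name + term values by curie

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class IngestOptions:
    hemizygous: bool = False  # single alleles on an X-linked gene
    created: str = "2024-01-01T00:00:00Z"
    created_by: str = "phenocurate"


def _read_raw(path: Path, format: str) -> list[list[str]]:
    if format == "csv":
        df = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    elif format == "xlsx":
        df = pd.read_excel(path, header=None, dtype=str, engine="openpyxl")
        df = df.fillna("")
    else:
        raise FormatError(f"unsupported template format {format!r}")
    return [[str(c).strip() for c in row] for row in df.itertuples(index=False)]


def read_template(path: str | Path, format: str | None = None) -> CurationTable:
    """Read a CSV/TSV/XLSX curation template (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix)
        if format is None:
            raise FormatError(f"cannot infer template format from {path.name!r}")
    grid = _read_raw(path, format)
    if len(grid) < 2:
        raise FormatError(f"{path}: template needs two header rows")
    labels, markers = grid[0], grid[1]

    fixed_index: dict[str, int] = {}
    term_columns: list[tuple[str, TermId]] = []
    term_index: list[tuple[int, TermId]] = []
    seen_curies: set[str] = set()
    for col, (label, marker) in enumerate(zip(labels, markers)):
        if HPO_PATTERN.match(marker):
            if marker in seen_curies:
                raise FormatError(f"{path}: term column {marker} listed twice")
            seen_curies.add(marker)
            curie = TermId(marker)
            term_columns.append((label, curie))
            term_index.append((col, curie))
        elif label in FIXED_COLUMNS:
            fixed_index[label] = col
    missing = [c for c in FIXED_COLUMNS if c not in fixed_index]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")

    rows = []
    for raw in grid[2:]:
        if not any(raw):
            continue
        row: dict[str, str] = {
            name: raw[col] if col < len(raw) else "" for name, col in fixed_index.items()
        }
        for col, curie in term_index:
            row[str(curie)] = raw[col] if col < len(raw) else ""
        rows.append(row)
    return CurationTable(fixed_index=fixed_index, term_columns=term_columns, rows=rows)


def _hgvs_syntax(value: str) -> HgvsSyntax | None:
    m = _HGVS_ANCHOR.search(value)
    if m is None:
        return None
    return {"c": HgvsSyntax.HGVS_C, "g": HgvsSyntax.HGVS_G, "p": HgvsSyntax.HGVS_P}[
        m.group(1)
    ]


def _descriptor(
    allele: str, transcript: str, gene: GeneContext, zygosity: OntologyClass, rank: int
) -> VariationDescriptor:
    value = allele
    if transcript and re.match(r"^[cgp]\.", allele):
        value = f"{transcript}:{allele}"
    syntax = _hgvs_syntax(value)
    if syntax is None:
        # no HGVS anchor: keep the qualitative structural-variant wording
        return VariationDescriptor(
            id=f"allele-{rank}", gene=gene, allelic_state=zygosity, sv_label=allele
        )
    return VariationDescriptor(
        id=f"allele-{rank}",
        gene=gene,
        allelic_state=zygosity,
        expressions=[Expression(syntax, value)],
    )


def _zygosity(name: str) -> OntologyClass:
    from .model import ZYGOSITY

    return ZYGOSITY[name]


def row_to_phenopacket(
    table: CurationTable, row_index: int, options: IngestOptions | None = None
) -> Phenopacket:
    """Build one phenopacket from table row *row_index* (0-based)."""
    options = options or IngestOptions()
    row = table.rows[row_index]

    def cell(name: str) -> str:
        return row.get(name, "")

    def age_cell(name: str) -> AgeValue | None:
        raw = cell(name)
        if raw in ("", "na"):
            return None
        try:
            return parse_age(raw)
        except ParseError as exc:
            raise CellError(str(exc), row=row_index, column=name) from exc

    sex_raw = cell("sex").lower()
    if sex_raw not in _SEX_MAP:
        raise CellError(f"unrecognized sex value {cell('sex')!r}", row=row_index,
                        column="sex")
    deceased_raw = cell("deceased").lower()
    if deceased_raw in ("", "na"):
        deceased = None
    elif deceased_raw in ("yes", "true", "y"):
        deceased = True
    elif deceased_raw in ("no", "false", "n"):
        deceased = False
    else:
        raise CellError(
            f"unrecognized deceased value {cell('deceased')!r}",
            row=row_index, column="deceased",
        )

    subject = Individual(
        id=cell("individual_id") or "individual",
        sex=_SEX_MAP[sex_raw],
        time_at_last_encounter=age_cell("age_at_last_encounter"),
        deceased=deceased,
    )

    features = []
    for label, curie in table.term_columns:
        raw = row.get(str(curie), "")
        if raw in ("", "na"):
            continue
        if raw == "observed":
            features.append(PhenotypicFeature(OntologyClass(curie, label)))
        elif raw == "excluded":
            features.append(PhenotypicFeature(OntologyClass(curie, label), excluded=True))
        else:
            try:
                onset = parse_age(raw)
            except ParseError as exc:
                raise CellError(
                    f"cell must be observed/excluded/na or an ISO age, got {raw!r}",
                    row=row_index, column=str(curie),
                ) from exc
            features.append(PhenotypicFeature(OntologyClass(curie, label), onset=onset))

    disease = OntologyClass(TermId(cell("disease_id")), cell("disease_label"))
    diseases = [DiseaseDx(term=disease, onset=age_cell("age_of_onset"))]

    interpretations = []
    a1, a2 = cell("allele_1"), cell("allele_2")
    if a1:
        gene = GeneContext(hgnc_id=cell("hgnc_id"), symbol=cell("gene_symbol"))
        transcript = cell("transcript")
        if a2 and a1 == a2:
            descriptors = [_descriptor(a1, transcript, gene, _zygosity("homozygous"), 1)]
        elif a2:
            descriptors = [
                _descriptor(a1, transcript, gene, _zygosity("heterozygous"), 1),
                _descriptor(a2, transcript, gene, _zygosity("heterozygous"), 2),
            ]
        else:
            state = "hemizygous" if options.hemizygous else "heterozygous"
            descriptors = [_descriptor(a1, transcript, gene, _zygosity(state), 1)]
        interpretations.append(
            Interpretation(
                id=f"{subject.id}-interpretation",
                diagnosis_disease=disease,
                genomic_interpretations=[
                    GenomicInterpretation(InterpretationStatus.CAUSATIVE, d)
                    for d in descriptors
                ],
            )
        )

    prefixes = ["HP", disease.id.prefix]
    if interpretations:
        prefixes += ["GENO", "HGNC"]
    return Phenopacket(
        id=make_phenopacket_id(cell("PMID"), cell("individual_id")),
        subject=subject,
        phenotypic_features=features,
        diseases=diseases,
        interpretations=interpretations,
        meta_data=MetaDataBlock(
            created=options.created,
            created_by=options.created_by,
            resources=resources_for(prefixes),
        ),
    )


@dataclass
class IngestResult:
    written: int
    issues: list[ValidationIssue] = field(default_factory=list)
    row_failures: list[str] = field(default_factory=list)


def ingest(
    table: CurationTable,
    ontology: OntologyGraph,
    out_dir: str | Path,
    options: IngestOptions | None = None,
    cfg: RuleConfig | None = None,
) -> IngestResult:
    """Convert every row, validate the batch, and write the clean packets.

    Only phenopackets with zero ERROR-level findings are written (one JSON
    file per individual, named by phenopacket id); the full issue list and
    any row-level conversion failures are returned, and an ``issues.tsv``
    report is placed next to the corpus.
    """
    from .pjson import write_phenopacket
    from .validate import issue_report

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    packets = []
    failures = []
    for i in range(table.n_rows):
        try:
            packets.append(row_to_phenopacket(table, i, options))
        except Exception as exc:  # cell/format problems are per-row findings
            failures.append(f"row {i}: {exc}")
    issues = validate_corpus(packets, ontology, cfg)
    bad_ids = {i.phenopacket_id for i in issues if i.level is Level.ERROR}
    written = 0
    for p in packets:
        if p.id in bad_ids:
            continue
        write_phenopacket(p, out_dir / f"{p.id}.json")
        written += 1
    (out_dir / "issues.tsv").write_text(issue_report(issues, "tsv"), encoding="utf-8")
    return IngestResult(written=written, issues=issues, row_failures=failures)
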