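"""Canonical JSON persistence for phenopackets, one individual per file.

Output follows the protobuf JSON mapping conventions used by reference
phenopacket tooling: lowerCamelCase keys, enums as strings, default-valued
fields (false, empty lists, UNKNOWN_SEX) omitted rather than written as
null, keys in schema declaration order, two-space indent, trailing newline.
The form is canonical — equal objects serialize to byte-identical files —
so corpus releases diff cleanly.

Input is forgiving: both lowerCamelCase and snake_case spellings are
accepted, and unknown keys are collected as warnings rather than rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .errors import EmptyCorpusError, FormatError, PhenocurateError
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
    Phenopacket,
    PhenotypicFeature,
    ProgressStatus,
    Resource,
    Sex,
    TermId,
    VariationDescriptor,
)

__all__ = [
    "phenopacket_to_dict",
    "phenopacket_from_dict",
    "write_phenopacket",
    "read_phenopacket",
    "read_corpus",
    "CorpusReadResult",
]


# ---------------------------------------------------------------- serialization

def _age_element(a: AgeValue | None) -> dict | None:
    return None if a is None else {"age": {"iso8601duration": a.iso8601}}


def _ontology_class(c: OntologyClass) -> dict:
    return {"id": str(c.id), "label": c.label}


def _prune(d: dict[str, Any]) -> dict[str, Any]:
    """Drop keys whose value is a protobuf default: None, False, [] or {}."""
    return {k: v for k, v in d.items() if v not in (None, False) and v != [] and v != {}}


def _subject_dict(s: Individual) -> dict:
    return _prune(
        {
            "id": s.id,
            "sex": None if s.sex is Sex.UNKNOWN_SEX else s.sex.value,
            "timeAtLastEncounter": _age_element(s.time_at_last_encounter),
            "deceased": s.deceased,
            "ageOfDeath": _age_element(s.age_of_death),
        }
    )


def _feature_dict(f: PhenotypicFeature) -> dict:
    return _prune(
        {
            "type": _ontology_class(f.type),
            "excluded": f.excluded,
            "onset": _age_element(f.onset),
        }
    )


def _descriptor_dict(v: VariationDescriptor) -> dict:
    return _prune(
        {
            "id": v.id,
            "geneContext": {"valueId": v.gene.hgnc_id, "symbol": v.gene.symbol},
            "expressions": [
                {"syntax": e.syntax.value, "value": e.value} for e in v.expressions
            ],
            "label": v.sv_label,
            "allelicState": _ontology_class(v.allelic_state),
        }
    )


def _interpretation_dict(i: Interpretation) -> dict:
    return {
        "id": i.id,
        "progressStatus": i.progress_status.value,
        "diagnosis": _prune(
            {
                "disease": _ontology_class(i.diagnosis_disease),
                "genomicInterpretations": [
                    {
                        "interpretationStatus": gi.status.value,
                        "variantInterpretation": {
                            "variationDescriptor": _descriptor_dict(gi.descriptor)
                        },
                    }
                    for gi in i.genomic_interpretations
                ],
            }
        ),
    }


def phenopacket_to_dict(p: Phenopacket) -> dict:
    """Render a phenopacket as a JSON-ready dict in canonical key order."""
    doc: dict[str, Any] = {
        "id": p.id,
        "subject": _subject_dict(p.subject),
        "phenotypicFeatures": [_feature_dict(f) for f in p.phenotypic_features],
        "diseases": [
            _prune({"term": _ontology_class(d.term), "onset": _age_element(d.onset)})
            for d in p.diseases
        ],
        "interpretations": [_interpretation_dict(i) for i in p.interpretations],
    }
    if p.meta_data is not None:
        doc["metaData"] = _prune(
            {
                "created": p.meta_data.created,
                "createdBy": p.meta_data.created_by,
                "resources": [
                    {
                        "id": r.id,
                        "name": r.name,
                        "url": r.url,
                        "version": r.version,
                        "namespacePrefix": r.namespace_prefix,
                        "iriPrefix": r.iri_prefix,
                    }
                    for r in p.meta_data.resources
                ],
                "phenopacketSchemaVersion": p.meta_data.schema_version,
            }
        )
    return _prune(doc)


def write_phenopacket(p: Phenopacket, path: str | Path) -> None:
    """Write one phenopacket as canonical UTF-8 JSON (2-space indent,
    trailing newline)."""
    path = Path(path)
    text = json.dumps(phenopacket_to_dict(p), indent=2, ensure_ascii=False) + "\n"
    path.write_text(text, encoding="utf-8")


# -------------------------------------------------------------- deserialization

def _snake(camel: str) -> str:
    out = []
    for ch in camel:
        if ch.isupper():
            out.append("_")
            out.append(ch.lower())
        else:
            out.append(ch)
    return "".join(out)


class _Reader:
    """Dialect-tolerant dict reader that tracks unconsumed keys."""

    def __init__(self, data: dict, path: str, warnings: list[str]):
        if not isinstance(data, dict):
            raise FormatError(f"{path}: expected an object")
        self.data = data
        self.path = path
        self.warnings = warnings
        self.consumed: set[str] = set()

    def get(self, camel: str, default: Any = None) -> Any:
        for key in (camel, _snake(camel)):
            if key in self.data:
                self.consumed.add(key)
                return self.data[key]
        return default

    def require(self, camel: str) -> Any:
        value = self.get(camel)
        if value is None:
            raise FormatError(f"{self.path}: missing required key {camel!r}")
        return value

    def sub(self, camel: str, required: bool = False) -> "_Reader | None":
        raw = self.require(camel) if required else self.get(camel)
        if raw is None:
            return None
        return _Reader(raw, f"{self.path}.{camel}", self.warnings)

    def finish(self) -> None:
        for key in self.data:
            if key not in self.consumed:
                self.warnings.append(f"{self.path}: unknown key {key!r}")


def _read_age(r: _Reader | None) -> AgeValue | None:
    if r is None:
        return None
    age = r.sub("age")
    r.finish()
    if age is None:
        return None
    iso = age.get("iso8601duration")
    age.finish()
    return None if iso is None else AgeValue(iso)


def _read_class(r: _Reader) -> OntologyClass:
    c = OntologyClass(TermId(r.require("id")), r.require("label"))
    r.finish()
    return c


def _read_subject(r: _Reader) -> Individual:
    subject = Individual(
        id=r.require("id"),
        sex=Sex[r.get("sex", "UNKNOWN_SEX")],
        time_at_last_encounter=_read_age(r.sub("timeAtLastEncounter")),
        deceased=r.get("deceased"),
        age_of_death=_read_age(r.sub("ageOfDeath")),
    )
    r.finish()
    return subject


def _read_descriptor(r: _Reader) -> VariationDescriptor:
    gc = r.sub("geneContext", required=True)
    gene = GeneContext(gc.require("valueId"), gc.require("symbol"))
    gc.finish()
    expressions = []
    for raw in r.get("expressions", []):
        er = _Reader(raw, f"{r.path}.expressions", r.warnings)
        expressions.append(Expression(HgvsSyntax(er.require("syntax")), er.require("value")))
        er.finish()
    desc = VariationDescriptor(
        id=r.require("id"),
        gene=gene,
        allelic_state=_read_class(r.sub("allelicState", required=True)),
        expressions=expressions,
        sv_label=r.get("label"),
    )
    r.finish()
    return desc


def _read_interpretation(r: _Reader) -> Interpretation:
    diag = r.sub("diagnosis", required=True)
    genomic = []
    for raw in diag.get("genomicInterpretations", []):
        gr = _Reader(raw, f"{diag.path}.genomicInterpretations", r.warnings)
        vi = gr.sub("variantInterpretation", required=True)
        genomic.append(
            GenomicInterpretation(
                status=InterpretationStatus(gr.require("interpretationStatus")),
                descriptor=_read_descriptor(vi.sub("variationDescriptor", required=True)),
            )
        )
        vi.finish()
        gr.finish()
    disease = _read_class(diag.sub("disease", required=True))
    diag.finish()
    interp = Interpretation(
        id=r.require("id"),
        diagnosis_disease=disease,
        genomic_interpretations=genomic,
        progress_status=ProgressStatus(r.get("progressStatus", "SOLVED")),
    )
    r.finish()
    return interp


def _read_metadata(r: _Reader | None) -> MetaDataBlock | None:
    if r is None:
        return None
    resources = []
    for raw in r.get("resources", []):
        rr = _Reader(raw, f"{r.path}.resources", r.warnings)
        resources.append(
            Resource(
                id=rr.require("id"),
                name=rr.require("name"),
                url=rr.require("url"),
                version=rr.require("version"),
                namespace_prefix=rr.require("namespacePrefix"),
                iri_prefix=rr.require("iriPrefix"),
            )
        )
        rr.finish()
    block = MetaDataBlock(
        created=r.require("created"),
        created_by=r.require("createdBy"),
        resources=resources,
        schema_version=r.get("phenopacketSchemaVersion", "2.0"),
    )
    r.finish()
    return block


def phenopacket_from_dict(
    data: dict, source: str = "<dict>", warnings: list[str] | None = None
) -> Phenopacket:
    """Build a phenopacket from a parsed JSON object.

    Accepts both camelCase and snake_case key spellings; unknown keys are
    appended to *warnings* (if given) and otherwise ignored.
    """
    sink = warnings if warnings is not None else []
    r = _Reader(data, source, sink)
    features = []
    for raw in r.get("phenotypicFeatures", []):
        fr = _Reader(raw, f"{source}.phenotypicFeatures", sink)
        features.append(
            PhenotypicFeature(
                type=_read_class(fr.sub("type", required=True)),
                excluded=bool(fr.get("excluded", False)),
                onset=_read_age(fr.sub("onset")),
            )
        )
        fr.finish()
    diseases = []
    for raw in r.get("diseases", []):
        dr = _Reader(raw, f"{source}.diseases", sink)
        diseases.append(
            DiseaseDx(
                term=_read_class(dr.sub("term", required=True)),
                onset=_read_age(dr.sub("onset")),
            )
        )
        dr.finish()
    packet = Phenopacket(
        id=r.require("id"),
        subject=_read_subject(r.sub("subject", required=True)),
        phenotypic_features=features,
        diseases=diseases,
        interpretations=[
            _read_interpretation(_Reader(raw, f"{source}.interpretations", sink))
            for raw in r.get("interpretations", [])
        ],
        meta_data=_read_metadata(r.sub("metaData")),
    )
    r.finish()
    return packet


def read_phenopacket(path: str | Path, warnings: list[str] | None = None) -> Phenopacket:
    """Read one phenopacket JSON file; invariants are enforced on construction."""
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return phenopacket_from_dict(data, source=str(path), warnings=warnings)


@dataclass
class CorpusReadResult:
    phenopackets: list[Phenopacket]
    failures: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return len(self.phenopackets)


def read_corpus(directory: str | Path) -> CorpusReadResult:
    """Load every ``*.json`` file under *directory* (recursively).

    Files are visited in stable path order. Per-file failures are recorded
    and skipped; only a corpus with zero readable phenopackets is an error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    result = CorpusReadResult([])
    for path in sorted(directory.rglob("*.json"), key=lambda p: p.as_posix()):
        try:
            result.phenopackets.append(read_phenopacket(path, warnings=result.warnings))
        except PhenocurateError as exc:
            result.failures.append((str(path), str(exc)))
    if not result.phenopackets:
        raise EmptyCorpusError(
            f"{directory}: no readable phenopackets "
            f"({len(result.failures)} failures)"
        )
    return result
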