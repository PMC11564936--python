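"""Quality-control rule engine for phenopackets and corpora.

The curation conventions of a literature-derived phenopacket corpus are
enforced as a registry of named rules. Per-phenopacket rules check id
format, the diagnosis/disease cross-reference, and ontology consistency of
the HPO annotations; corpus rules check id uniqueness. Findings are data
(:class:`ValidationIssue`), never exceptions, so a whole corpus can be
audited in one pass.

Ontology consistency rests on annotation propagation: an observed term
implies all its ancestors, and an excluded term implies exclusion of all
its descendants. An observed term with an excluded ancestor is therefore a
logical contradiction (ERROR); an observed term alongside an observed
ancestor is merely redundant (WARNING).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

from .model import Phenopacket, pmid_of, PHENOPACKET_ID_PATTERN
from .ontology import OntologyGraph

__all__ = [
    "Level",
    "ValidationIssue",
    "RuleConfig",
    "RULE_REGISTRY",
    "validate_phenopacket",
    "validate_corpus",
    "issue_report",
]


class Level(enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


#: rule id → (default level, short description)
RULE_REGISTRY: dict[str, tuple[Level, str]] = {
    "R1": (Level.ERROR, "phenopacket id must match PMID_<digits>_<id>"),
    "R2": (Level.ERROR, "interpretation diagnosis must cite a listed disease"),
    "R3": (Level.ERROR, "feature term must exist in the ontology"),
    "R4": (Level.WARNING, "feature term is obsolete"),
    "R5": (Level.WARNING, "feature label must match the ontology label"),
    "R6": (Level.ERROR, "observed feature conflicts with an excluded ancestor"),
    "R7": (Level.WARNING, "redundant feature (subsumed by another annotation)"),
    "R8": (Level.WARNING, "onset later than age at last encounter"),
    "R9": (Level.WARNING, "CURIE prefix lacks a metadata resource"),
    "R10": (Level.WARNING, "more than one disease entry"),
    "C1": (Level.ERROR, "duplicate phenopacket id in corpus"),
    "C2": (Level.ERROR, "duplicate (PMID, individual) pair in corpus"),
}


@dataclass
class ValidationIssue:
    level: Level
    rule_id: str
    phenopacket_id: str
    message: str

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_REGISTRY:
            raise ValueError(f"unknown rule id {self.rule_id!r}")


@dataclass
class RuleConfig:
    """Per-rule enable flags and ERROR/WARNING level overrides."""

    disabled: set[str] = field(default_factory=set)
    levels: dict[str, Level] = field(default_factory=dict)

    def level(self, rule_id: str) -> Level | None:
        """Effective level of a rule, or None if the rule is disabled."""
        if rule_id in self.disabled:
            return None
        return self.levels.get(rule_id, RULE_REGISTRY[rule_id][0])


_DEFAULT_CFG = RuleConfig()


class _Sink:
    def __init__(self, cfg: RuleConfig, packet_id: str):
        self.cfg = cfg
        self.packet_id = packet_id
        self.issues: list[ValidationIssue] = []

    def emit(self, rule_id: str, message: str) -> None:
        level = self.cfg.level(rule_id)
        if level is not None:
            self.issues.append(ValidationIssue(level, rule_id, self.packet_id, message))


def _used_prefixes(p: Phenopacket) -> set[str]:
    prefixes = set()
    for f in p.phenotypic_features:
        prefixes.add(f.type.id.prefix)
    for d in p.diseases:
        prefixes.add(d.term.id.prefix)
    for i in p.interpretations:
        prefixes.add(i.diagnosis_disease.id.prefix)
        for gi in i.genomic_interpretations:
            prefixes.add(gi.descriptor.allelic_state.id.prefix)
            prefixes.add(gi.descriptor.gene.hgnc_id.partition(":")[0])
    return prefixes


def validate_phenopacket(
    p: Phenopacket, g: OntologyGraph, cfg: RuleConfig | None = None
) -> list[ValidationIssue]:
    """Apply every per-phenopacket rule; returns findings, never raises."""
    cfg = cfg or _DEFAULT_CFG
    sink = _Sink(cfg, p.id)

    # R1 id format
    if not PHENOPACKET_ID_PATTERN.match(p.id):
        sink.emit("R1", f"id {p.id!r} does not match PMID_<digits>_<id>")

    # R2 diagnosis cross-reference
    disease_ids = {str(d.term.id) for d in p.diseases}
    for interp in p.interpretations:
        dx = str(interp.diagnosis_disease.id)
        if dx not in disease_ids:
            sink.emit(
                "R2",
                f"interpretation {interp.id!r} cites {dx}, which is not in the "
                f"disease list {sorted(disease_ids)}",
            )

    # R3/R4/R5 per-term checks; terms absent from the ontology are skipped by
    # the semantic rules below.
    known = []
    for f in p.phenotypic_features:
        tid = f.type.id
        if tid not in g:
            sink.emit("R3", f"term {tid} not found in the ontology")
            continue
        known.append(f)
        if g.is_obsolete(tid):
            sink.emit("R4", f"term {tid} ({g.label_of(tid)}) is obsolete")
        if f.type.label != g.label_of(tid):
            sink.emit(
                "R5",
                f"label {f.type.label!r} for {tid} differs from ontology "
                f"label {g.label_of(tid)!r}",
            )

    observed = {f.type.id for f in known if not f.excluded}
    excluded = {f.type.id for f in known if f.excluded}

    # R6 conflict: an observed term whose ancestor-or-self is excluded.
    for t in sorted(observed):
        clash = g.ancestors(t, include_self=True) & excluded
        if clash:
            sink.emit(
                "R6",
                f"observed {t} conflicts with excluded ancestor(s) "
                f"{sorted(map(str, clash))}",
            )

    # R7 redundancy: observed term with an observed proper ancestor; excluded
    # term with an excluded proper descendant.
    for t in sorted(observed):
        above = g.ancestors(t) & observed
        if above:
            sink.emit(
                "R7",
                f"observed {t} is subsumed by observed ancestor(s) "
                f"{sorted(map(str, above))}",
            )
    for t in sorted(excluded):
        below = g.descendants(t) & excluded
        if below:
            sink.emit(
                "R7",
                f"excluded {t} already covers excluded descendant(s) "
                f"{sorted(map(str, below))}",
            )

    # R8 onset ordering against age at last encounter
    last = p.subject.time_at_last_encounter
    if last is not None:
        for f in p.phenotypic_features:
            if f.onset is not None and f.onset.total_days() > last.total_days():
                sink.emit(
                    "R8",
                    f"feature {f.type.id} onset {f.onset.iso8601} is later than "
                    f"last encounter {last.iso8601}",
                )
        for d in p.diseases:
            if d.onset is not None and d.onset.total_days() > last.total_days():
                sink.emit(
                    "R8",
                    f"disease {d.term.id} onset {d.onset.iso8601} is later than "
                    f"last encounter {last.iso8601}",
                )

    # R9 metadata resource coverage of CURIE prefixes
    declared = (
        {r.namespace_prefix for r in p.meta_data.resources} if p.meta_data else set()
    )
    for prefix in sorted(_used_prefixes(p) - declared):
        sink.emit("R9", f"prefix {prefix} has no metadata resource")

    # R10 corpus convention: one disease per phenopacket
    if len(p.diseases) > 1:
        sink.emit("R10", f"{len(p.diseases)} disease entries (corpus convention is 1)")

    return sink.issues


def validate_corpus(
    packets: list[Phenopacket], g: OntologyGraph, cfg: RuleConfig | None = None
) -> list[ValidationIssue]:
    """All per-phenopacket findings plus corpus-level uniqueness rules."""
    cfg = cfg or _DEFAULT_CFG
    issues: list[ValidationIssue] = []
    for p in packets:
        issues.extend(validate_phenopacket(p, g, cfg))

    # C1: duplicate phenopacket ids — every duplicate beyond the first.
    seen_ids: set[str] = set()
    for p in packets:
        sink = _Sink(cfg, p.id)
        if p.id in seen_ids:
            sink.emit("C1", f"phenopacket id {p.id!r} occurs more than once")
        seen_ids.add(p.id)
        issues.extend(sink.issues)

    # C2: duplicate (PMID, individual id) pairs.
    seen_pairs: set[tuple[str, str]] = set()
    for p in packets:
        pmid = pmid_of(p.id)
        if pmid is None:
            continue
        pair = (pmid, p.subject.id)
        sink = _Sink(cfg, p.id)
        if pair in seen_pairs:
            sink.emit(
                "C2",
                f"individual {p.subject.id!r} appears more than once in PMID {pmid}",
            )
        seen_pairs.add(pair)
        issues.extend(sink.issues)

    return issues


def issue_report(issues: list[ValidationIssue], format: str = "tsv") -> str:
    """Render findings as TSV (level/rule/phenopacket/message) or JSON,
    sorted by (level desc, rule id, phenopacket id) for stable diffs."""
    ordered = sorted(
        issues,
        key=lambda i: (i.level is not Level.ERROR, i.rule_id, i.phenopacket_id, i.message),
    )
    if format == "tsv":
        lines = ["level\trule_id\tphenopacket_id\tmessage"]
        for i in ordered:
            lines.append(
                f"{i.level.value}\t{i.rule_id}\t{i.phenopacket_id}\t{i.message}"
            )
        return "\n".join(lines) + "\n"
    if format == "json":
        return (
            json.dumps(
                [
                    {
                        "level": i.level.value,
                        "rule_id": i.rule_id,
                        "phenopacket_id": i.phenopacket_id,
                        "message": i.message,
                    }
                    for i in ordered
                ],
                indent=2,
            )
            + "\n"
        )
    raise ValueError(f"unknown report format {format!r}")
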