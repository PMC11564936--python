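"""QC rule engine: per-rule behavior, the propagation oracle, and reports."""

import pytest

from phenocurate.model import (
    DiseaseDx,
    Individual,
    OntologyClass,
    Phenopacket,
    PhenotypicFeature,
    TermId,
    parse_age,
)
from phenocurate.validate import (
    Level,
    RuleConfig,
    issue_report,
    validate_corpus,
    validate_phenopacket,
)

from conftest import make_graph, random_dag

import numpy as np


def packet(**kwargs) -> Phenopacket:
    from phenocurate.model import MetaDataBlock
    from phenocurate.resources import resources_for

    defaults = dict(
        id="PMID_1_a",
        subject=Individual(id="a"),
        meta_data=MetaDataBlock(
            created="2024-01-01T00:00:00Z",
            created_by="test",
            resources=resources_for(["HP", "OMIM"]),
        ),
    )
    defaults.update(kwargs)
    return Phenopacket(**defaults)


def feature(tid: str, label: str = None, excluded: bool = False, onset: str = None):
    return PhenotypicFeature(
        OntologyClass(TermId(tid), label or f"term {tid}"),
        excluded=excluded,
        onset=None if onset is None else parse_age(onset),
    )


class TestDiagnosisRule:
    def test_diagnosis_must_cite_listed_disease(self, chain_graph):
        from phenocurate.model import Interpretation

        p = packet(
            diseases=[DiseaseDx(term=OntologyClass(TermId("OMIM:101600"), "Pfeiffer"))],
            interpretations=[
                Interpretation(
                    id="i1",
                    diagnosis_disease=OntologyClass(TermId("OMIM:616868"), "Diarrhea 8"),
                )
            ],
        )
        issues = validate_phenopacket(p, chain_graph)
        r2 = [i for i in issues if i.rule_id == "R2"]
        assert len(r2) == 1 and r2[0].level is Level.ERROR

    def test_matching_diagnosis_is_clean(self, chain_graph):
        from phenocurate.model import Interpretation

        dx = OntologyClass(TermId("OMIM:616868"), "Diarrhea 8")
        p = packet(
            diseases=[DiseaseDx(term=dx)],
            interpretations=[Interpretation(id="i1", diagnosis_disease=dx)],
        )
        assert [i for i in validate_phenopacket(p, chain_graph) if i.rule_id == "R2"] == []


class TestOntologyRules:
    def test_observed_child_with_excluded_parent_is_conflict(self, chain_graph):
        p = packet(
            phenotypic_features=[
                feature("HP:9000003"),  # child observed
                feature("HP:9000002", excluded=True),  # parent excluded
            ]
        )
        issues = validate_phenopacket(p, chain_graph)
        assert [i.rule_id for i in issues if i.level is Level.ERROR] == ["R6"]

    def test_same_term_observed_and_excluded_is_conflict(self, chain_graph):
        p = packet(
            phenotypic_features=[
                feature("HP:9000003"),
                feature("HP:9000003", excluded=True),
            ]
        )
        assert ["R6"] == [
            i.rule_id for i in validate_phenopacket(p, chain_graph)
            if i.level is Level.ERROR
        ]

    def test_observed_ancestor_of_observed_is_redundant(self, chain_graph):
        p = packet(phenotypic_features=[feature("HP:9000002"), feature("HP:9000003")])
        issues = validate_phenopacket(p, chain_graph)
        assert [i.rule_id for i in issues] == ["R7"]
        assert issues[0].level is Level.WARNING

    def test_unknown_term_is_error_and_skips_semantic_rules(self, chain_graph):
        p = packet(phenotypic_features=[feature("HP:8888888")])
        assert [i.rule_id for i in validate_phenopacket(p, chain_graph)] == ["R3"]

    def test_obsolete_term_warns(self):
        g = make_graph(
            {"HP:9000001": [], "HP:9000002": ["HP:9000001"]},
            root="HP:9000001",
            obsolete={"HP:9000002"},
        )
        p = packet(phenotypic_features=[feature("HP:9000002")])
        assert "R4" in [i.rule_id for i in validate_phenopacket(p, g)]

    def test_label_mismatch_warns(self, chain_graph):
        p = packet(phenotypic_features=[feature("HP:9000003", label="wrong label")])
        assert "R5" in [i.rule_id for i in validate_phenopacket(p, chain_graph)]

    def test_conflict_and_redundancy_match_propagation_oracle(self):
        """R6/R7 agree with materializing the full propagated annotation sets."""
        rng = np.random.default_rng(13)
        parents = random_dag(rng, 30)
        g = make_graph(parents, root=next(iter(parents)))
        nodes = sorted(parents)
        for trial in range(50):
            drawn = rng.choice(len(nodes), size=6, replace=False)
            observed = {nodes[i] for i in drawn[:3]}
            excluded = {nodes[i] for i in drawn[3:]}
            p = packet(
                phenotypic_features=[feature(t) for t in sorted(observed)]
                + [feature(t, excluded=True) for t in sorted(excluded)]
            )
            issues = validate_phenopacket(p, g)
            has_r6 = any(i.rule_id == "R6" for i in issues)
            has_r7 = any(i.rule_id == "R7" for i in issues)
            # oracle: propagate observed up, excluded down, intersect
            obs_closure = set().union(
                *({t} | g.ancestors(t) for t in observed)
            )
            exc_closure = set().union(
                *({t} | g.descendants(t) for t in excluded)
            )
            assert has_r6 == bool(obs_closure & exc_closure)
            oracle_r7 = any(
                g.is_ancestor(a, b)
                for a in observed for b in observed
            ) or any(
                g.is_ancestor(a, b)
                for a in excluded for b in excluded
            )
            assert has_r7 == oracle_r7


class TestOtherRules:
    def test_onset_after_last_encounter_warns(self, chain_graph):
        p = packet(
            subject=Individual(id="a", time_at_last_encounter=parse_age("P2Y")),
            phenotypic_features=[feature("HP:9000003", onset="P5Y")],
        )
        assert "R8" in [i.rule_id for i in validate_phenopacket(p, chain_graph)]

    def test_bad_id_flagged_not_raised(self, chain_graph):
        p = packet()
        p.id = "nonsense"  # post-construction mutation, as a corrupt file would be
        assert "R1" in [i.rule_id for i in validate_phenopacket(p, chain_graph)]

    def test_multi_disease_warns(self, chain_graph):
        p = packet(
            diseases=[
                DiseaseDx(term=OntologyClass(TermId("OMIM:900001"), "d1")),
                DiseaseDx(term=OntologyClass(TermId("OMIM:900002"), "d2")),
            ]
        )
        assert "R10" in [i.rule_id for i in validate_phenopacket(p, chain_graph)]

    def test_missing_resource_prefix_warns(self, chain_graph):
        p = packet(
            diseases=[DiseaseDx(term=OntologyClass(TermId("OMIM:900001"), "d1"))],
            meta_data=None,  # no resources declared at all
        )
        assert "R9" in [i.rule_id for i in validate_phenopacket(p, chain_graph)]

    def test_clean_synthetic_corpus_has_no_findings(self, small_corpus):
        g, packets, _ = small_corpus
        assert validate_corpus(packets, g) == []

    def test_duplicate_ids_error_per_extra_copy(self, chain_graph):
        a, b, c = packet(), packet(), packet()
        b.subject.id = "b"
        c.subject.id = "c"
        issues = [
            i for i in validate_corpus([a, b, c], chain_graph) if i.rule_id == "C1"
        ]
        assert len(issues) == 2  # each duplicate beyond the first

    def test_duplicate_individual_within_publication(self, chain_graph):
        a = packet()
        b = packet(id="PMID_1_b")
        b.subject.id = "a"  # same individual id, same PMID, different packet id
        issues = [
            i for i in validate_corpus([a, b], chain_graph) if i.rule_id == "C2"
        ]
        assert len(issues) == 1


class TestConfigAndReport:
    def test_disabled_rule_is_silent(self, chain_graph):
        p = packet(phenotypic_features=[feature("HP:8888888")])
        cfg = RuleConfig(disabled={"R3"})
        assert validate_phenopacket(p, chain_graph, cfg) == []

    def test_level_override(self, chain_graph):
        p = packet(phenotypic_features=[feature("HP:9000003", label="wrong")])
        cfg = RuleConfig(levels={"R5": Level.ERROR})
        issues = validate_phenopacket(p, chain_graph, cfg)
        assert issues and all(i.level is Level.ERROR for i in issues)

    def test_report_formats_and_determinism(self, chain_graph):
        p = packet(
            phenotypic_features=[
                feature("HP:8888888"),
                feature("HP:9000003", label="wrong"),
            ]
        )
        issues = validate_phenopacket(p, chain_graph)
        tsv = issue_report(issues, "tsv")
        lines = tsv.strip().split("\n")
        assert lines[0] == "level\trule_id\tphenopacket_id\tmessage"
        assert len(lines) == 3
        assert lines[1].startswith("ERROR")  # errors sort first
        assert issue_report(list(reversed(issues)), "tsv") == tsv
        assert issue_report([], "tsv").strip().count("\n") == 0

    def test_validation_is_pure(self, small_corpus):
        g, packets, _ = small_corpus
        assert validate_corpus(packets, g) == validate_corpus(packets, g)
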