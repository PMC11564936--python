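"""Seeded synthetic ontologies and phenopacket corpora with planted truth.

Real literature-curated corpora are large external downloads; every stage of
this package is instead exercised against synthetic corpora that emulate
their structure: gene cohorts, one OMIM-style disease per individual, allele
pools with occasional qualitative structural variants, per-individual
present/excluded HPO annotation counts, ages, sexes, and PMIDs.

Two properties make the generator a sharp oracle:

* **Rule-cleanliness by construction.** Feature sets are sampled from the
  ontology's leaves, which form an antichain of the is_a DAG, and observed
  and excluded draws are disjoint — so no annotation subsumes another and
  no exclusion contradicts an observation. A fresh corpus validates with
  zero findings, which makes :func:`inject_faults` the *only* source of
  violations.
* **Recorded ground truth.** Every count a cohort summary could report is
  tallied while the corpus is built, so statistics can be checked exactly.

Default rates mirror a published rare-disease case-report corpus: 8.2
present and 11.8 excluded annotations per individual, 4.3% of annotations
with an age of onset, sex specified for 75.6% of individuals (52.8% of
those male), 1.1 diseases and 2.29 publications per gene cohort.

Synthetic identifiers are visibly fake but structurally valid: HP terms in
the 9xxxxxx range, OMIM ids in 9xxxxx, PMIDs from 90000000.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ArgumentError
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
    Sex,
    TermId,
    VariationDescriptor,
    make_phenopacket_id,
)
from .ontology import OntologyGraph, OntologyTerm
from .resources import resources_for

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_ontology",
    "write_ontology",
    "generate_corpus",
    "write_corpus",
    "inject_faults",
    "INJECTABLE_RULES",
]

SV_LABEL = "gene deletion"
SYNTHETIC_CREATED = "2024-01-01T00:00:00Z"
SYNTHETIC_CREATOR = "phenocurate-simulator"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults are the corpus conditions the
    generator emulates (see module docstring)."""

    seed: int = 0
    n_genes: int = 10
    mean_cohort_size: float = 15.8
    mean_diseases_per_gene: float = 1.1
    mean_publications_per_cohort: float = 2.29
    mean_present: float = 8.2
    mean_excluded: float = 11.8
    p_onset: float = 0.043
    p_sex_specified: float = 0.756
    p_male_given_specified: float = 0.528
    p_age_specified: float = 0.9
    p_deceased: float = 0.05
    allele_pool_size: int = 8
    p_sv_allele: float = 0.1
    p_homozygous: float = 0.2
    p_compound_het: float = 0.3
    ontology_depth: int = 4
    ontology_branching: int = 3
    n_obsolete_terms: int = 5
    n_extra_edges: int = 10

    def __post_init__(self) -> None:
        for name in (
            "p_onset",
            "p_sex_specified",
            "p_male_given_specified",
            "p_age_specified",
            "p_deceased",
            "p_sv_allele",
            "p_homozygous",
            "p_compound_het",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ArgumentError(f"{name} must be a probability, got {v}")
        if self.n_genes < 1 or self.allele_pool_size < 1:
            raise ArgumentError("n_genes and allele_pool_size must be >= 1")
        if self.ontology_depth < 1 or self.ontology_branching < 1:
            raise ArgumentError("ontology depth and branching must be >= 1")


@dataclass
class GroundTruth:
    """Counts recorded while the corpus was built (not re-derived from it)."""

    n_phenopackets: int = 0
    n_cohorts: int = 0
    n_features: int = 0
    n_present: int = 0
    n_excluded: int = 0
    n_onset_features: int = 0
    n_sex_specified: int = 0
    n_male: int = 0
    n_with_age: int = 0
    n_distinct_diseases: int = 0
    per_cohort: dict[str, dict[str, int]] = field(default_factory=dict)
    per_disease_counts: dict[str, int] = field(default_factory=dict)
    config: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


# ------------------------------------------------------------------- ontology

def generate_ontology(cfg: GeneratorConfig) -> OntologyGraph:
    """Build a rooted is_a DAG of HP-style terms, deterministic in the seed.

    A complete tree of the configured depth/branching is grown first, then a
    few extra child→shallower-internal edges turn it into a proper DAG.
    Leaves never acquire children, so the leaf set stays an antichain.
    Obsolete terms hang off the root and are never sampled into corpora.
    """
    rng = np.random.default_rng(cfg.seed)
    counter = 9000000
    levels: list[list[TermId]] = []
    terms: dict[TermId, OntologyTerm] = {}

    def new_term(label: str, obsolete: bool = False) -> TermId:
        nonlocal counter
        tid = TermId(f"HP:{counter}")
        counter += 1
        terms[tid] = OntologyTerm(id=tid, label=label, obsolete=obsolete)
        return tid

    root = new_term("Synthetic phenotypic abnormality")
    levels.append([root])
    for depth in range(1, cfg.ontology_depth + 1):
        level: list[TermId] = []
        for parent in levels[-1]:
            for b in range(cfg.ontology_branching):
                child = new_term(f"Synthetic term d{depth} #{len(level) + 1}")
                terms[child].parents.add(parent)
                level.append(child)
        levels.append(level)

    internal = [t for lvl in levels[:-1] for t in lvl]
    non_root = [t for lvl in levels[1:] for t in lvl]
    depth_of = {t: d for d, lvl in enumerate(levels) for t in lvl}
    added = 0
    guard = 0
    while added < cfg.n_extra_edges and guard < 100 * cfg.n_extra_edges:
        guard += 1
        child = non_root[int(rng.integers(len(non_root)))]
        parent = internal[int(rng.integers(len(internal)))]
        if depth_of[parent] >= depth_of[child] or parent in terms[child].parents:
            continue
        terms[child].parents.add(parent)
        added += 1

    for i in range(cfg.n_obsolete_terms):
        tid = new_term(f"Obsolete synthetic term #{i + 1}", obsolete=True)
        terms[tid].parents.add(root)

    return OntologyGraph(terms, root)


def write_ontology(g: OntologyGraph, path: str | Path) -> None:
    """Write the graph as an obographs-style JSON file (is_a edges only)."""
    nodes = []
    edges = []
    for t in sorted(g.terms.values(), key=lambda t: t.id):
        node: dict = {"id": str(t.id), "lbl": t.label}
        if t.obsolete:
            node["meta"] = {"deprecated": True}
        nodes.append(node)
        for parent in sorted(t.parents):
            edges.append({"sub": str(t.id), "pred": "is_a", "obj": str(parent)})
    doc = {"graphs": [{"nodes": nodes, "edges": edges}]}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


# --------------------------------------------------------------------- corpus

def _shifted_poisson(rng: np.random.Generator, mean: float, minimum: int = 1) -> int:
    """Draw ``minimum + Poisson(mean - minimum)``; keeps sizes >= minimum."""
    lam = max(mean - minimum, 0.0)
    return minimum + int(rng.poisson(lam))


def _months_to_iso(months: int) -> AgeValue:
    y, m = divmod(months, 12)
    if y and m:
        return AgeValue(f"P{y}Y{m}M")
    if y:
        return AgeValue(f"P{y}Y")
    return AgeValue(f"P{m}M" if m else "P0D")


def _draw_sex(rng: np.random.Generator, cfg: GeneratorConfig) -> Sex:
    if rng.random() >= cfg.p_sex_specified:
        return Sex.UNKNOWN_SEX
    return Sex.MALE if rng.random() < cfg.p_male_given_specified else Sex.FEMALE


def generate_corpus(
    cfg: GeneratorConfig, g: OntologyGraph
) -> tuple[list[Phenopacket], GroundTruth]:
    """Generate a rule-clean corpus plus its recorded ground truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    leaves = sorted(
        t.id for t in g.terms.values()
        if not t.obsolete and not g.descendants(t.id)
    )
    if len(leaves) < 3:
        raise ArgumentError("ontology has too few leaves to sample annotations")

    truth = GroundTruth(config=asdict(cfg))
    packets: list[Phenopacket] = []
    pmid_counter = 90000000
    omim_counter = 900000
    individual_counter = 0

    for gi in range(cfg.n_genes):
        symbol = f"GENE{gi + 1}"
        gene = GeneContext(hgnc_id=f"HGNC:{90000 + gi}", symbol=symbol)
        transcript = f"NM_9{gi:04d}.1"

        n_dis = _shifted_poisson(rng, cfg.mean_diseases_per_gene)
        diseases = []
        for _ in range(n_dis):
            omim_counter += 1
            diseases.append(
                OntologyClass(
                    TermId(f"OMIM:{omim_counter}"),
                    f"Synthetic disease {omim_counter}",
                )
            )

        n_pub = _shifted_poisson(rng, cfg.mean_publications_per_cohort)
        pmids = []
        for _ in range(n_pub):
            pmid_counter += 1
            pmids.append(str(pmid_counter))

        pool: list[tuple[str, str | None]] = []  # (hgvs value, None) or (label, "sv")
        has_sv = False
        for j in range(cfg.allele_pool_size):
            if not has_sv and rng.random() < cfg.p_sv_allele:
                pool.append((SV_LABEL, "sv"))
                has_sv = True
            else:
                pool.append((f"{transcript}:c.{100 + 17 * j}A>G", None))

        cohort_size = _shifted_poisson(rng, cfg.mean_cohort_size)
        cohort_counts = {
            "n_phenopackets": 0,
            "n_diseases": 0,
            "n_unique_alleles": 0,
            "n_publications": 0,
            "n_present_annotations": 0,
            "n_excluded_annotations": 0,
            "n_distinct_terms": 0,
        }
        used_diseases: set[str] = set()
        used_alleles: set[int] = set()
        used_pmids: set[str] = set()
        used_terms: set[str] = set()

        for _ in range(cohort_size):
            individual_counter += 1
            subj_id = f"individual_{individual_counter}"
            pmid = pmids[int(rng.integers(len(pmids)))]
            disease = diseases[int(rng.integers(len(diseases)))]
            used_pmids.add(pmid)
            used_diseases.add(str(disease.id))
            truth.per_disease_counts[str(disease.id)] = (
                truth.per_disease_counts.get(str(disease.id), 0) + 1
            )

            # ages
            age = None
            age_months = None
            if rng.random() < cfg.p_age_specified:
                age_months = int(rng.integers(1, 960))
                age = _months_to_iso(age_months)
            sex = _draw_sex(rng, cfg)
            deceased = None
            age_of_death = None
            if rng.random() < cfg.p_deceased:
                deceased = True
                if age_months is not None:
                    age_of_death = _months_to_iso(age_months + int(rng.integers(0, 24)))
            subject = Individual(
                id=subj_id,
                sex=sex,
                time_at_last_encounter=age,
                deceased=deceased,
                age_of_death=age_of_death,
            )

            # annotations: disjoint leaf draws keep the packet rule-clean
            n_present = max(1, int(rng.poisson(cfg.mean_present)))
            n_excl = int(rng.poisson(cfg.mean_excluded))
            n_present = min(n_present, len(leaves) - 1)
            n_excl = min(n_excl, len(leaves) - n_present)
            drawn = rng.choice(len(leaves), size=n_present + n_excl, replace=False)
            features = []
            for idx, leaf_i in enumerate(drawn):
                tid = leaves[leaf_i]
                is_excluded = idx >= n_present
                onset = None
                if rng.random() < cfg.p_onset:
                    if age_months is not None:
                        onset = _months_to_iso(int(rng.integers(0, age_months + 1)))
                    else:
                        onset = _months_to_iso(int(rng.integers(0, 240)))
                    truth.n_onset_features += 1
                features.append(
                    PhenotypicFeature(
                        type=OntologyClass(tid, g.label_of(tid)),
                        excluded=is_excluded,
                        onset=onset,
                    )
                )
                used_terms.add(str(tid))

            # alleles and interpretation
            u = rng.random()
            if u < cfg.p_homozygous:
                a = int(rng.integers(len(pool)))
                allele_idx = [a, a]
            elif u < cfg.p_homozygous + cfg.p_compound_het and len(pool) >= 2:
                a, b = rng.choice(len(pool), size=2, replace=False)
                allele_idx = [int(a), int(b)]
            else:
                allele_idx = [int(rng.integers(len(pool)))]

            descriptors = []
            if len(allele_idx) == 2 and allele_idx[0] == allele_idx[1]:
                zyg = "homozygous"
                alleles = [allele_idx[0]]
            else:
                zyg = "heterozygous"
                alleles = allele_idx
            for rank, ai in enumerate(alleles):
                value, kind = pool[ai]
                used_alleles.add(ai)
                state = OntologyClass(
                    TermId("GENO:0000136" if zyg == "homozygous" else "GENO:0000135"),
                    zyg,
                )
                if kind == "sv":
                    descriptors.append(
                        VariationDescriptor(
                            id=f"var_{individual_counter}_{rank}",
                            gene=gene,
                            allelic_state=state,
                            sv_label=value,
                        )
                    )
                else:
                    descriptors.append(
                        VariationDescriptor(
                            id=f"var_{individual_counter}_{rank}",
                            gene=gene,
                            allelic_state=state,
                            expressions=[Expression(HgvsSyntax.HGVS_C, value)],
                        )
                    )

            interpretation = Interpretation(
                id=f"{subj_id}-interpretation",
                diagnosis_disease=disease,
                genomic_interpretations=[
                    GenomicInterpretation(InterpretationStatus.CAUSATIVE, d)
                    for d in descriptors
                ],
            )

            packet_id = make_phenopacket_id(pmid, subj_id)
            packet = Phenopacket(
                id=packet_id,
                subject=subject,
                phenotypic_features=features,
                diseases=[DiseaseDx(term=disease)],
                interpretations=[interpretation],
                meta_data=MetaDataBlock(
                    created=SYNTHETIC_CREATED,
                    created_by=SYNTHETIC_CREATOR,
                    resources=resources_for(["HP", "OMIM", "GENO", "HGNC"]),
                ),
            )
            packets.append(packet)

            cohort_counts["n_phenopackets"] += 1
            cohort_counts["n_present_annotations"] += n_present
            cohort_counts["n_excluded_annotations"] += n_excl
            truth.n_features += n_present + n_excl
            truth.n_present += n_present
            truth.n_excluded += n_excl
            if sex is not Sex.UNKNOWN_SEX:
                truth.n_sex_specified += 1
                if sex is Sex.MALE:
                    truth.n_male += 1
            if age is not None:
                truth.n_with_age += 1

        cohort_counts["n_diseases"] = len(used_diseases)
        cohort_counts["n_unique_alleles"] = len(used_alleles)
        cohort_counts["n_publications"] = len(used_pmids)
        cohort_counts["n_distinct_terms"] = len(used_terms)
        truth.per_cohort[symbol] = cohort_counts
        truth.n_phenopackets += cohort_size
        truth.n_distinct_diseases += len(used_diseases)

    truth.n_cohorts = cfg.n_genes
    return packets, truth


def write_corpus(packets: list[Phenopacket], out_dir: str | Path) -> list[Path]:
    """Write one JSON file per phenopacket, named by its id."""
    from .pjson import write_phenopacket

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in packets:
        path = out_dir / f"{p.id}.json"
        write_phenopacket(p, path)
        paths.append(path)
    return paths


# ------------------------------------------------------------- fault injection

INJECTABLE_RULES = ("R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8", "R9", "R10",
                    "C1", "C2")


def _conflict_sites(
    packets: list[Phenopacket], g: OntologyGraph, observed_side: bool
) -> list[tuple[int, TermId, TermId]]:
    """(packet index, target term, ancestor to add) triples where adding the
    ancestor as excluded (R6) or observed (R7) creates exactly one finding."""
    sites = []
    for pi, p in enumerate(packets):
        observed = {f.type.id for f in p.phenotypic_features if not f.excluded}
        excluded = {f.type.id for f in p.phenotypic_features if f.excluded}
        for t in sorted(observed):
            for anc in sorted(g.ancestors(t)):
                if anc == g.root or anc in observed or anc in excluded:
                    continue
                desc = g.descendants(anc)
                if desc & observed != {t}:
                    continue
                if observed_side:
                    # new observed ancestor: must not itself be subsumed or clash
                    if g.ancestors(anc) & observed or g.ancestors(anc) & excluded:
                        continue
                else:
                    # new excluded ancestor: no excluded term above or below it
                    if desc & excluded or g.ancestors(anc) & excluded:
                        continue
                sites.append((pi, t, anc))
                break  # one site per packet keeps counts independent
            else:
                continue
            break
    return sites


def inject_faults(
    packets: list[Phenopacket],
    rule_id: str,
    k: int,
    seed: int,
    g: OntologyGraph | None = None,
) -> tuple[list[Phenopacket], list[str]]:
    """Return a deep-copied corpus with exactly *k* independent violations of
    *rule_id* planted, and the ids of the mutated phenopackets.

    Each injection is constructed so it triggers precisely one finding of the
    named rule and none of any other rule; this is what makes the generator a
    counting oracle for the validator.
    """
    if rule_id not in INJECTABLE_RULES:
        raise ArgumentError(f"cannot inject rule {rule_id!r}")
    if k < 0:
        raise ArgumentError("k must be >= 0")
    rng = np.random.default_rng(seed)
    mutated = copy.deepcopy(packets)
    if k == 0:
        return mutated, []
    if rule_id in ("R3", "R4", "R5", "R6", "R7") and g is None:
        raise ArgumentError(f"rule {rule_id} injection requires the ontology")

    def pick(indices: list[int], count: int) -> list[int]:
        if count > len(indices):
            raise ArgumentError(
                f"only {len(indices)} feasible sites for {rule_id}, need {count}"
            )
        chosen = rng.choice(len(indices), size=count, replace=False)
        return [indices[int(c)] for c in sorted(chosen)]

    touched: list[str] = []

    if rule_id == "R1":
        for pi in pick(list(range(len(mutated))), k):
            touched.append(mutated[pi].id)
            mutated[pi].id = "BADID_" + mutated[pi].id
    elif rule_id == "R2":
        sites = [i for i, p in enumerate(mutated) if p.interpretations]
        for pi in pick(sites, k):
            p = mutated[pi]
            p.interpretations[0].diagnosis_disease = OntologyClass(
                TermId("OMIM:999999"), "Mismatched synthetic disease"
            )
            touched.append(p.id)
    elif rule_id == "R3":
        sites = [i for i, p in enumerate(mutated) if p.phenotypic_features]
        for n, pi in enumerate(pick(sites, k)):
            p = mutated[pi]
            f = p.phenotypic_features[0]
            f.type = OntologyClass(TermId(f"HP:{8000000 + n}"), "Unknown synthetic term")
            touched.append(p.id)
    elif rule_id == "R4":
        assert g is not None
        obsolete = sorted(t.id for t in g.terms.values() if t.obsolete)
        if not obsolete:
            raise ArgumentError("ontology has no obsolete terms to inject")
        sites = [i for i, p in enumerate(mutated) if p.phenotypic_features]
        for n, pi in enumerate(pick(sites, k)):
            p = mutated[pi]
            tid = obsolete[n % len(obsolete)]
            p.phenotypic_features[0].type = OntologyClass(tid, g.label_of(tid))
            touched.append(p.id)
    elif rule_id == "R5":
        sites = [i for i, p in enumerate(mutated) if p.phenotypic_features]
        for pi in pick(sites, k):
            p = mutated[pi]
            f = p.phenotypic_features[0]
            f.type = OntologyClass(f.type.id, f.type.label + " (renamed)")
            touched.append(p.id)
    elif rule_id in ("R6", "R7"):
        assert g is not None
        all_sites = _conflict_sites(mutated, g, observed_side=(rule_id == "R7"))
        if k > len(all_sites):
            raise ArgumentError(
                f"only {len(all_sites)} feasible sites for {rule_id}, need {k}"
            )
        chosen = rng.choice(len(all_sites), size=k, replace=False)
        for ci in sorted(int(c) for c in chosen):
            pi, _, anc = all_sites[ci]
            p = mutated[pi]
            p.phenotypic_features.append(
                PhenotypicFeature(
                    type=OntologyClass(anc, g.label_of(anc)),
                    excluded=(rule_id == "R6"),
                )
            )
            touched.append(p.id)
    elif rule_id == "R8":
        sites = [
            i
            for i, p in enumerate(mutated)
            if p.subject.time_at_last_encounter is not None and p.phenotypic_features
        ]
        for pi in pick(sites, k):
            p = mutated[pi]
            last = p.subject.time_at_last_encounter
            months = int(round(last.total_days() / 30.437)) + 13
            p.phenotypic_features[0].onset = _months_to_iso(months)
            touched.append(p.id)
    elif rule_id == "R9":
        sites = [
            i
            for i, p in enumerate(mutated)
            if p.meta_data is not None
            and p.interpretations
            and any(r.namespace_prefix == "GENO" for r in p.meta_data.resources)
        ]
        for pi in pick(sites, k):
            p = mutated[pi]
            p.meta_data.resources = [
                r for r in p.meta_data.resources if r.namespace_prefix != "GENO"
            ]
            touched.append(p.id)
    elif rule_id == "R10":
        for n, pi in enumerate(pick(list(range(len(mutated))), k)):
            p = mutated[pi]
            p.diseases.append(
                DiseaseDx(
                    term=OntologyClass(
                        TermId(f"OMIM:{998000 + n}"), "Extra synthetic disease"
                    )
                )
            )
            touched.append(p.id)
    elif rule_id == "C1":
        by_pmid: dict[str, list[int]] = {}
        from .model import pmid_of

        for i, p in enumerate(mutated):
            pm = pmid_of(p.id)
            if pm:
                by_pmid.setdefault(pm, []).append(i)
        pmids = sorted(by_pmid)
        pairs = []
        used: set[int] = set()
        for a in range(len(pmids)):
            for b in range(a + 1, len(pmids)):
                i = next((x for x in by_pmid[pmids[a]] if x not in used), None)
                j = next((x for x in by_pmid[pmids[b]] if x not in used), None)
                if i is not None and j is not None:
                    pairs.append((i, j))
                    used.update((i, j))
                break
        if k > len(pairs):
            raise ArgumentError(f"only {len(pairs)} feasible sites for C1, need {k}")
        chosen = rng.choice(len(pairs), size=k, replace=False)
        for ci in sorted(int(c) for c in chosen):
            i, j = pairs[ci]
            mutated[j].id = mutated[i].id
            touched.append(mutated[j].id)
    elif rule_id == "C2":
        from .model import pmid_of

        by_pmid = {}
        for i, p in enumerate(mutated):
            pm = pmid_of(p.id)
            if pm:
                by_pmid.setdefault(pm, []).append(i)
        pairs = []
        for pm in sorted(by_pmid):
            members = by_pmid[pm]
            for a in range(0, len(members) - 1, 2):
                pairs.append((members[a], members[a + 1]))
        if k > len(pairs):
            raise ArgumentError(f"only {len(pairs)} feasible sites for C2, need {k}")
        chosen = rng.choice(len(pairs), size=k, replace=False)
        for ci in sorted(int(c) for c in chosen):
            i, j = pairs[ci]
            mutated[j].subject.id = mutated[i].subject.id
            touched.append(mutated[j].id)

    return mutated, touched
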