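"""Gene-cohort partitioning and corpus summary statistics.

A curated corpus is summarized the way rare-disease collections report
themselves: individuals are partitioned into cohorts by the gene harboring
the causal variant, each cohort is tallied (phenopackets, distinct diseases,
unique alleles, publications, present/excluded annotation counts), and an
aggregate table gives mean/median/min/max/total per column. Per-individual
summaries cover annotation counts, sex, age at last encounter, and the
fraction of annotations carrying an age of onset.

Conventions: allele identity is the literal HGVS string (or the qualitative
SV label) together with the gene symbol — no normalization; publication
identity is the PMID embedded in the phenopacket id; means are rounded
half-up to one decimal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .model import Phenopacket, Sex, pmid_of

logger = logging.getLogger(__name__)

__all__ = [
    "NO_GENE_KEY",
    "CohortSummary",
    "CorpusTable",
    "IndividualSummary",
    "round1",
    "partition_by_gene",
    "summarize_cohort",
    "corpus_table",
    "individual_summaries",
    "age_histogram",
]

NO_GENE_KEY = "_NO_GENE_"


def round1(x: float) -> float:
    """Round half-up to one decimal (the table convention; Python's
    bankers' rounding would turn 0.25 into 0.2)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _gene_of(p: Phenopacket) -> str | None:
    for interp in p.interpretations:
        for gi in interp.genomic_interpretations:
            return gi.descriptor.gene.symbol
    return None


def partition_by_gene(packets: list[Phenopacket]) -> dict[str, list[Phenopacket]]:
    """Group phenopackets by the gene symbol of the first genomic
    interpretation. Packets without one go under ``_NO_GENE_`` and are
    excluded from cohort aggregates."""
    cohorts: dict[str, list[Phenopacket]] = {}
    for p in packets:
        gene = _gene_of(p)
        if gene is None:
            cohorts.setdefault(NO_GENE_KEY, []).append(p)
        else:
            cohorts.setdefault(gene, []).append(p)
    n_orphan = len(cohorts.get(NO_GENE_KEY, []))
    if n_orphan:
        logger.info("%d phenopackets have no genomic interpretation", n_orphan)
    return cohorts


@dataclass
class CohortSummary:
    """Tallies for one gene cohort."""

    gene_symbol: str
    n_phenopackets: int
    n_diseases: int
    n_unique_alleles: int
    n_publications: int
    n_present_annotations: int
    n_excluded_annotations: int
    n_distinct_terms: int

    def __post_init__(self) -> None:
        if self.n_phenopackets < 1:
            raise ValueError("a cohort must contain at least one phenopacket")

    @property
    def n_total_annotations(self) -> int:
        return self.n_present_annotations + self.n_excluded_annotations


def summarize_cohort(gene_symbol: str, cohort: list[Phenopacket]) -> CohortSummary:
    diseases: set[str] = set()
    alleles: set[tuple[str, str]] = set()
    pmids: set[str] = set()
    terms: set[str] = set()
    n_present = n_excluded = 0
    multi_gene = 0
    for p in cohort:
        for d in p.diseases:
            diseases.add(str(d.term.id))
        genes_here = set()
        for interp in p.interpretations:
            for gi in interp.genomic_interpretations:
                alleles.add(gi.descriptor.allele_key())
                genes_here.add(gi.descriptor.gene.symbol)
        if len(genes_here) > 1:
            multi_gene += 1
        pmid = pmid_of(p.id)
        if pmid is not None:
            pmids.add(pmid)
        for f in p.phenotypic_features:
            terms.add(str(f.type.id))
            if f.excluded:
                n_excluded += 1
            else:
                n_present += 1
    if multi_gene:
        logger.info(
            "cohort %s: %d phenopackets cite more than one gene", gene_symbol, multi_gene
        )
    return CohortSummary(
        gene_symbol=gene_symbol,
        n_phenopackets=len(cohort),
        n_diseases=len(diseases),
        n_unique_alleles=len(alleles),
        n_publications=len(pmids),
        n_present_annotations=n_present,
        n_excluded_annotations=n_excluded,
        n_distinct_terms=len(terms),
    )


_COLUMNS = (
    "n_phenopackets",
    "n_diseases",
    "n_unique_alleles",
    "n_publications",
    "n_present_annotations",
    "n_excluded_annotations",
    "n_total_annotations",
)


@dataclass
class CorpusTable:
    """Cohort rows plus aggregate mean/median/min/max/total rows.

    ``per_disease`` carries the distribution of phenopacket counts when the
    corpus is grouped by distinct disease id instead of by gene; its mean is
    total phenopackets over distinct diseases.
    """

    rows: list[CohortSummary]
    mean: dict[str, float]
    median: dict[str, float]
    minimum: dict[str, int]
    maximum: dict[str, int]
    total: dict[str, int]
    per_disease: dict[str, float] = field(default_factory=dict)

    def to_tsv(self) -> str:
        header = ["gene_symbol", *_COLUMNS]
        lines = ["\t".join(header)]
        for r in self.rows:
            lines.append(
                "\t".join([r.gene_symbol] + [str(getattr(r, c)) for c in _COLUMNS])
            )
        for name, agg in (
            ("Mean", self.mean),
            ("Median", self.median),
            ("Minimum", self.minimum),
            ("Maximum", self.maximum),
            ("Total", self.total),
        ):
            lines.append("\t".join([name] + [str(agg[c]) for c in _COLUMNS]))
        return "\n".join(lines) + "\n"


def _median(values: list[float]) -> float:
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    if n % 2:
        return float(vals[mid])
    return (vals[mid - 1] + vals[mid]) / 2.0


def corpus_table(
    summaries: list[CohortSummary],
    per_disease_counts: list[int] | None = None,
) -> CorpusTable:
    """Aggregate cohort summaries into the five-row summary table.

    *per_disease_counts*, when given, is the list of phenopacket counts per
    distinct disease (the alternative grouping of the same corpus).
    """
    if not summaries:
        raise ValueError("corpus_table needs at least one cohort summary")
    mean: dict[str, float] = {}
    median: dict[str, float] = {}
    minimum: dict[str, int] = {}
    maximum: dict[str, int] = {}
    total: dict[str, int] = {}
    for col in _COLUMNS:
        values = [getattr(s, col) for s in summaries]
        total[col] = sum(values)
        mean[col] = round1(total[col] / len(values))
        median[col] = _median(values)
        minimum[col] = min(values)
        maximum[col] = max(values)
    per_disease: dict[str, float] = {}
    if per_disease_counts:
        per_disease = {
            "mean": round1(sum(per_disease_counts) / len(per_disease_counts)),
            "median": _median(per_disease_counts),
            "minimum": min(per_disease_counts),
            "maximum": max(per_disease_counts),
            "total": sum(per_disease_counts),
        }
    return CorpusTable(
        rows=list(summaries),
        mean=mean,
        median=median,
        minimum=minimum,
        maximum=maximum,
        total=total,
        per_disease=per_disease,
    )


def disease_counts(packets: list[Phenopacket]) -> list[int]:
    """Phenopacket count per distinct disease id (first listed disease)."""
    counts: dict[str, int] = {}
    for p in packets:
        if p.diseases:
            key = str(p.diseases[0].term.id)
            counts[key] = counts.get(key, 0) + 1
    return sorted(counts.values(), reverse=True)


@dataclass
class IndividualSummary:
    phenopacket_id: str
    n_present: int
    n_excluded: int
    sex: Sex
    age_last_encounter_years: float | None


def individual_summaries(
    packets: list[Phenopacket],
) -> tuple[list[IndividualSummary], dict[str, object]]:
    """Per-individual annotation tallies plus corpus-level aggregates.

    The aggregate dict carries mean present/excluded counts (totals over n),
    sex counts, the percentage of individuals with sex specified, the male
    percentage among those, and the percentage of annotations with an age of
    onset — each percentage rounded half-up to one decimal. Sex ratios are
    absent (None) when no individual has sex specified.
    """
    rows: list[IndividualSummary] = []
    n_with_onset = 0
    n_features = 0
    sex_counts = {s: 0 for s in Sex}
    for p in packets:
        present = excluded = 0
        for f in p.phenotypic_features:
            n_features += 1
            if f.onset is not None:
                n_with_onset += 1
            if f.excluded:
                excluded += 1
            else:
                present += 1
        sex_counts[p.subject.sex] += 1
        age = p.subject.time_at_last_encounter
        rows.append(
            IndividualSummary(
                phenopacket_id=p.id,
                n_present=present,
                n_excluded=excluded,
                sex=p.subject.sex,
                age_last_encounter_years=None if age is None else age.total_years(),
            )
        )
    n = len(packets)
    n_specified = sum(
        c for s, c in sex_counts.items() if s in (Sex.MALE, Sex.FEMALE, Sex.OTHER_SEX)
    )
    aggregate: dict[str, object] = {
        "n_individuals": n,
        "n_features": n_features,
        "mean_present": round1(sum(r.n_present for r in rows) / n) if n else None,
        "mean_excluded": round1(sum(r.n_excluded for r in rows) / n) if n else None,
        "sex_counts": {s.value: c for s, c in sex_counts.items()},
        "pct_sex_specified": round1(100.0 * n_specified / n) if n else None,
        "pct_male_of_specified": (
            round1(100.0 * sex_counts[Sex.MALE] / n_specified) if n_specified else None
        ),
        "onset_fraction": (
            round1(100.0 * n_with_onset / n_features) if n_features else None
        ),
        "n_features_with_onset": n_with_onset,
    }
    return rows, aggregate


def age_histogram(
    packets: list[Phenopacket], bin_width_years: float = 5.0
) -> dict[str, object]:
    """Histogram of ages at last encounter, overall and by sex.

    Bins are half-open ``[k*w, (k+1)*w)``; individuals without an age are
    counted separately, not binned.
    """
    if bin_width_years <= 0:
        raise ValueError("bin width must be positive")
    overall: dict[int, int] = {}
    by_sex: dict[str, dict[int, int]] = {}
    n_missing = 0
    for p in packets:
        age = p.subject.time_at_last_encounter
        if age is None:
            n_missing += 1
            continue
        k = int(math.floor(age.total_years() / bin_width_years))
        overall[k] = overall.get(k, 0) + 1
        sex_bins = by_sex.setdefault(p.subject.sex.value, {})
        sex_bins[k] = sex_bins.get(k, 0) + 1
    return {
        "bin_width_years": bin_width_years,
        "overall": dict(sorted(overall.items())),
        "by_sex": {s: dict(sorted(b.items())) for s, b in sorted(by_sex.items())},
        "n_without_age": n_missing,
    }
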