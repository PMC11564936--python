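# phenocurate

Tools for building, validating and summarizing corpora of **GA4GH-style
phenopackets** — structured, case-level records of the phenotypic features,
disease diagnosis and causal variant of one individual, as curated from
published rare-disease case reports.

Deep phenotyping projects turn supplementary tables of the medical genetics
literature into machine-readable corpora: one JSON phenopacket per patient,
phenotypes encoded with Human Phenotype Ontology (HPO) terms asserted
*present* or explicitly *excluded*, diagnoses encoded with OMIM/Mondo ids,
and variants carried as HGVS expressions (or a verbatim qualitative label
such as "gene deletion" for structural variants known only from a
microarray report). This package implements that curation stack for
biocurators and the bioinformaticians who consume such corpora:

- a **typed phenopacket model** with the PubMed-based id convention
  (`PMID_<pmid>_<individual>`, e.g. `PMID_24126608_BAB3022`) and ISO 8601
  age algebra;
- **canonical JSON persistence** — camelCase keys, defaults omitted,
  byte-stable output, one individual per file, tolerant snake_case input;
- an **obographs ontology loader** answering the one reasoning question QC
  needs: ancestor closure over `is_a` edges;
- **tabular ingest** of a two-header-row curation template (rows =
  individuals, one column per HPO term, cells `observed`/`excluded`/`na`/an
  onset age);
- a **QC rule engine** (rules R1–R10 per phenopacket, C1–C2 per corpus)
  built on annotation propagation: an observed term implies its ancestors,
  an excluded term excludes its descendants, so an observed term under an
  excluded ancestor is a logical contradiction and an annotated
  ancestor/descendant pair on the same side is redundancy;
- **cohort statistics**: individuals partitioned into gene cohorts by the
  causal variant's gene, per-cohort tallies (phenopackets, diseases, unique
  alleles, publications, present/excluded annotations) and the
  mean/median/min/max/total summary table;
- a seeded **synthetic-corpus generator** with planted, recorded ground
  truth and single-finding fault injection — the test harness for all of
  the above.

## Worked example

```python
from phenocurate import (
    GeneratorConfig, generate_ontology, generate_corpus, validate_corpus,
    partition_by_gene, summarize_cohort, corpus_table, individual_summaries,
    inject_faults, issue_report,
)

cfg = GeneratorConfig(seed=42, n_genes=5, mean_cohort_size=10)
g = generate_ontology(cfg)
packets, truth = generate_corpus(cfg, g)
print("phenopackets:", len(packets))
print("findings on clean corpus:", len(validate_corpus(packets, g)))

cohorts = partition_by_gene(packets)
summaries = [summarize_cohort(k, v) for k, v in sorted(cohorts.items())]
table = corpus_table(summaries)
print("mean cohort size:", table.mean["n_phenopackets"])
print("total annotations:", table.total["n_total_annotations"])

_, agg = individual_summaries(packets)
print("mean present/excluded per individual:",
      agg["mean_present"], "/", agg["mean_excluded"])

mutated, _ = inject_faults(packets, "R6", 2, seed=1, g=g)
print(issue_report(validate_corpus(mutated, g), "tsv"))
```

prints

```
phenopackets: 46
findings on clean corpus: 0
mean cohort size: 9.2
total annotations: 903
mean present/excluded per individual: 8.2 / 11.4
level	rule_id	phenopacket_id	message
ERROR	R6	PMID_90000003_individual_24	observed HP:9000050 conflicts with excluded ancestor(s) ['HP:9000016']
ERROR	R6	PMID_90000004_individual_22	observed HP:9000079 conflicts with excluded ancestor(s) ['HP:9000005']
```

A 5-gene corpus of 46 synthetic individuals validates clean by
construction; injecting two conflicts (an observed term whose ancestor is
excluded in the same packet) produces exactly those two ERROR findings and
nothing else. The per-individual annotation means reflect the generator's
defaults, which emulate a published literature-curated corpus (8.2 present
and 11.8 excluded terms per individual on average).

The same workflow is available from the shell:

```sh
phenocurate simulate --seed 42 --out sim/
phenocurate validate --corpus sim/corpus --ontology sim/ontology.json
phenocurate stats    --corpus sim/corpus --out cohorts.tsv
phenocurate ingest   --template cases.csv --ontology hp.json --out corpus/
```

`validate` exits 0 when no ERROR-level finding exists, 1 otherwise, and 2 on
usage or format problems — suitable as a corpus release gate in CI.

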