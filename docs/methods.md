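# Methods

## The data model

A phenopacket here is the subset of the GA4GH Phenopacket Schema that
literature-curated rare-disease corpora actually populate: a subject
(id, sex, age at last encounter, vital status), a list of phenotypic
features (HPO term, present or excluded, optional onset age), a disease
list (OMIM/Mondo), interpretations (diagnosis plus one or two variation
descriptors), and a metadata block resolving every CURIE prefix to an
ontology resource. Measurements, medical actions, biosamples and pedigrees
are out of scope.

Construction enforces local invariants (HPO pattern on feature ids, HGNC
pattern on gene ids, "HGVS expressions XOR qualitative SV label" on
descriptors, `age_of_death ⇒ deceased`, no duplicate (term, excluded)
assertion). Dataclasses stay mutable: a corrupt file read back into memory,
or a deliberately mutated test object, is re-checked by the validator
rather than being unrepresentable — validation findings are data, not
exceptions.

### Identifiers

Phenopacket ids follow the `PMID_<pubmed id>_<individual id>` convention
used by literature-curated corpora; the (PMID, individual) pair is the
uniqueness key across a corpus. The source publications never define legal
id characters, so sanitization is a declared convention of this package:
characters outside `[A-Za-z0-9_.-]` become `_`, runs collapse, edges are
stripped, and an id that vanishes entirely becomes `individual` (also the
stand-in when a publication names no id). The map is idempotent and keeps
ids filesystem- and URL-safe, since the corpus layout is one JSON file per
individual named by id.

### Ages

Ages are ISO 8601 durations restricted to Y/M/W/D. Comparison uses fixed
day counts — 365.25 d/year, 30.437 d/month, 7 d/week — chosen so ordering
is total, deterministic and testable; the slight asymmetry (1 year >
12 months by 0.006 d) is harmless for the only ordering question QC asks
(onset ≤ age at last encounter).

## Serialization

Output follows the protobuf JSON mapping conventions of reference
phenopacket tooling: lowerCamelCase keys, enums as strings, default values
(false, empty list, UNKNOWN_SEX) omitted rather than emitted as null, keys
in schema declaration order, two-space indent, trailing newline. Within
this convention a boolean false is indistinguishable from an absent key, so
the model normalizes `deceased=False` to unset. The form is canonical —
equal objects give byte-identical files — which is what makes corpus
releases diffable and the round-trip property testable. Input accepts both
camelCase and snake_case and collects unknown keys as warnings.

## Ontology handling

Only `is_a`/`subClassOf` edges are honored (other predicates are counted
and dropped); subsumption is the only reasoning QC needs. The graph is held
as a networkx DiGraph with child→parent edges, so ancestor closure is plain
reachability and cycle detection is standard. Obsolete terms load and are
flagged; using one is a validation warning rather than a load error,
because a corpus is routinely QC'd against an ontology release newer than
the one it was curated with — for the same reason the ontology file is an
explicit input, never pinned. If a file contains several parentless terms,
an internal virtual root (`OWL:Thing`) binds them so closure stays total;
it is never serialized and never appears in query results.

## The QC rule registry

| rule | level | checks |
|------|-------|--------|
| R1 | ERROR | id matches `PMID_<digits>_<id>` |
| R2 | ERROR | interpretation diagnosis id is in the disease list |
| R3 | ERROR | feature term exists in the ontology |
| R4 | WARNING | feature term is obsolete |
| R5 | WARNING | feature label equals the ontology label (case-sensitive) |
| R6 | ERROR | observed feature with an excluded ancestor-or-self |
| R7 | WARNING | observed feature subsumed by an observed ancestor; excluded feature covering an excluded descendant |
| R8 | WARNING | feature/disease onset later than age at last encounter |
| R9 | WARNING | a used CURIE prefix lacks a metadata resource |
| R10 | WARNING | more than one disease entry (corpus convention is one) |
| C1 | ERROR | duplicate phenopacket id (each copy beyond the first) |
| C2 | ERROR | duplicate (PMID, individual) pair |

Severity reflects consequence: a logical contradiction (R6) or a dangling
diagnosis reference (R2) blocks release; redundancy (R7) and label drift
(R5) are hygiene. Both are configurable per rule (enable flag, ERROR/WARNING
override) because different corpora draw the line differently. R6 includes
the self pair — the same term asserted present and excluded — which falls
out of the propagation semantics (observed ∪ ancestors intersected with
excluded ∪ descendants). R6/R7 findings attach per offending feature, one
finding regardless of how many witnesses, which gives fault injection an
exact counting contract. Detecting the *same person* published under two
different ids in two papers is deliberately not a rule; it is not decidable
from the data a phenopacket carries.

## Template ingest

The curation template dialect is fully specified here because source
descriptions of such templates are informal: two header rows (labels, then
HPO CURIEs for term columns and `str`/`age`/`optional` markers for the 14
fixed columns), and a four-way cell vocabulary — `observed`, `excluded`,
`na`/blank, or an ISO age meaning "present with this onset". Any other cell
text is an error carrying (row, column) coordinates: curation safety over
convenience. Alleles equal → one homozygous descriptor; distinct → two
heterozygous; single → heterozygous, or hemizygous on request (X-linked
genes). An allele without an HGVS anchor (`:c.`, `:g.`, `:p.`, or a bare
`c.`-style string completed by the transcript column) is kept verbatim as a
qualitative structural-variant label. Ingest converts every row, validates
the batch, and writes only packets with zero ERROR findings; when duplicate
rows collide on the same id, all copies are held back, since writing both
would silently overwrite one file.

## Cohort statistics

Cohorts are keyed by the gene symbol of the first genomic interpretation
(multi-gene packets are logged; packets without an interpretation are
bucketed under `_NO_GENE_` and excluded from aggregates). Allele identity
is the literal HGVS string or SV label plus gene symbol — no normalization,
because literal matching is reproducible and normalization semantics are
not derivable from qualitative labels. Publication identity is the PMID
embedded in the phenopacket id (single source of truth). Means are rounded
half-up to one decimal (`decimal`, not bankers' rounding). The aggregate
table's Total row is the column sum over cohort rows; the per-disease
column re-groups the same corpus by distinct disease id, and its mean is
total phenopackets over distinct diseases. A corpus in which a disease is
associated with two genes would count it once per cohort in the Diseases
column but once overall in the per-disease grouping; the synthetic
generator never produces that case, and real corpora that do should read
the Diseases total as a per-cohort sum. Per-individual aggregates
(mean present/excluded counts, onset percentage over all annotations, sex
percentages among individuals with sex specified) are totals over n; sex
ratios are reported as absent when no individual has sex specified.

## The synthetic generator

The generator emulates the structure of a literature-curated corpus, not
its biology. Defaults are the emulated corpus conditions: 8.2 present and
11.8 excluded annotations per individual (Poisson, present clamped ≥ 1),
onset on 4.3% of annotations, sex specified for 75.6% of individuals with
52.8% of those male, 1.1 diseases and 2.29 publications per gene cohort
(1 + Poisson), cohort sizes 1 + Poisson(mean − 1) around 15.8, an 8-allele
pool per gene with a ~10% chance of one qualitative "gene deletion" allele.
Identifiers are visibly fake but structurally valid (HP:9xxxxxx terms,
OMIM:9xxxxx diseases, PMIDs from 90000000).

Two design choices make it an oracle rather than a fixture. First,
annotations are sampled from the ontology's **leaves**, which form an
antichain, with observed and excluded draws disjoint — so a fresh corpus is
rule-clean by construction and `inject_faults` is the only source of
violations. Second, every count a cohort summary reports is **tallied
during generation**, so statistics are checked against recorded ground
truth, not re-derived. Fault injection picks its sites so each mutation
triggers exactly one finding of exactly the named rule (e.g. an R6
injection excludes an ancestor dominating exactly one observed term, with
no excluded term above or below it), giving k-in/k-out counting tests.

What the generator does **not** model: disease-specific phenotype
frequencies, correlated annotations, curation noise (typos, free-text
ages), heavy-tailed cohort sizes (the shifted Poisson has no 400-individual
tail), or real HPO's breadth. Passing tests therefore demonstrate that the
pipeline is correct on structurally faithful data, not that it is robust to
every artifact of real curation; the rule engine's behavior on messy input
is covered separately by the fault-injection and malformed-input tests.

### Onset on excluded annotations

Published onset fractions are quoted over *all* phenotype annotations, so
the generator plants onset per annotation regardless of excluded status and
the statistics module uses the same denominator; empirically recovered
rates then estimate the planted probability directly.

## Problem sizes and numerical choices

Tests run on corpora of tens to hundreds of phenopackets over ontologies of
~120 terms (depth 4, branching 3, plus 10 extra DAG edges and 5 obsolete
terms); the closure oracle uses 100 random DAGs of up to 50 nodes; the
parameter-recovery check uses ≥ 5,000 features and 3 binomial standard
errors; the acceptance script uses a 40-gene, ~600-individual corpus.
These sizes were chosen as the smallest at which every contract is
exercised with comfortable statistical margin. All randomness flows through
`numpy.random.default_rng` seeded from explicit configuration; identical
configuration gives byte-identical corpora. Half-up rounding to one decimal
is applied exactly where the summary table prints one decimal; raw counts
are never rounded.

## Known limitations

- HGVS strings are carried, not parsed; syntax validation against reference
  transcripts requires external services and is out of scope.
- The ontology loader implements the obographs subset (nodes, is_a edges,
  deprecation flags), not full OWL.
- Variant descriptors cover gene context, expressions, SV label and
  zygosity; no VRS normalization or sequence-level representation.
- The validator assumes one individual per phenopacket and cannot detect
  the same individual re-published under a different id.
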