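"""In-memory model of the phenopacket subset used for literature-curated
rare-disease case reports.

The model covers the elements such corpora actually populate — subject,
phenotypic features, diseases, interpretations, metadata — together with the
ID and age conventions used throughout: phenopacket ids of the form
``PMID_<pubmed id>_<individual id>``, and ages as ISO 8601 durations.

All dataclasses validate their invariants in ``__post_init__``; a constructed
object is always internally consistent. Cross-object conventions (diagnosis
ids resolving against the disease list, CURIE prefixes backed by metadata
resources) are the province of :mod:`phenocurate.validate`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from .errors import ArgumentError, ParseError, ValidationError

__all__ = [
    "TermId",
    "HPO_PATTERN",
    "Sex",
    "OntologyClass",
    "AgeValue",
    "parse_age",
    "compare_age",
    "Individual",
    "PhenotypicFeature",
    "DiseaseDx",
    "GeneContext",
    "Expression",
    "VariationDescriptor",
    "GenomicInterpretation",
    "Interpretation",
    "Resource",
    "MetaDataBlock",
    "Phenopacket",
    "make_phenopacket_id",
    "sanitize",
    "build_sv_descriptor",
    "pmid_of",
    "ZYGOSITY",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "2.0"

CURIE_PATTERN = re.compile(r"^[A-Za-z][A-Za-z0-9]*:[A-Za-z0-9.]+$")
HPO_PATTERN = re.compile(r"^HP:[0-9]{7}$")
PHENOPACKET_ID_PATTERN = re.compile(r"^PMID_\d+_[A-Za-z0-9_.-]+$")
HGNC_PATTERN = re.compile(r"^HGNC:\d+$")
ISO_DURATION_PATTERN = re.compile(r"^P(?:(\d+)Y)?(?:(\d+)M)?(?:(\d+)W)?(?:(\d+)D)?$")

# Fixed day counts make age comparison deterministic.
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.437
DAYS_PER_WEEK = 7.0


class TermId(str):
    """A CURIE of the form ``PREFIX:LOCALID`` (e.g. ``HP:0001250``).

    Behaves as a plain string; construction validates the pattern.
    """

    def __new__(cls, curie: str) -> "TermId":
        if not CURIE_PATTERN.match(curie):
            raise ParseError(f"not a valid CURIE: {curie!r}")
        return super().__new__(cls, curie)

    @property
    def prefix(self) -> str:
        return self.partition(":")[0]

    @property
    def local_id(self) -> str:
        return self.partition(":")[2]

    def is_hpo(self) -> bool:
        return HPO_PATTERN.match(self) is not None


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    OTHER_SEX = "OTHER_SEX"
    UNKNOWN_SEX = "UNKNOWN_SEX"


@dataclass
class OntologyClass:
    """An ontology term reference: id + human-readable label."""

    id: TermId
    label: str

    def __post_init__(self) -> None:
        if not isinstance(self.id, TermId):
            self.id = TermId(self.id)
        if not self.label:
            raise ValidationError(f"ontology class {self.id} has an empty label")


@dataclass(frozen=True)
class AgeValue:
    """An age as an ISO 8601 duration restricted to Y/M/W/D components."""

    iso8601: str

    def __post_init__(self) -> None:
        m = ISO_DURATION_PATTERN.match(self.iso8601)
        if m is None or not any(m.groups()):
            raise ParseError(f"not an ISO 8601 Y/M/W/D duration: {self.iso8601!r}")

    def total_days(self) -> float:
        y, mo, w, d = ISO_DURATION_PATTERN.match(self.iso8601).groups()
        return (
            int(y or 0) * DAYS_PER_YEAR
            + int(mo or 0) * DAYS_PER_MONTH
            + int(w or 0) * DAYS_PER_WEEK
            + int(d or 0)
        )

    def total_years(self) -> float:
        return self.total_days() / DAYS_PER_YEAR


def parse_age(text: str) -> AgeValue:
    """Parse an ISO 8601 duration string like ``P4Y2M`` into an :class:`AgeValue`.

    Only designators Y, M, W, D are accepted, in that order. Free-text ages
    ("4y", "32 weeks") are rejected; curation templates must use ISO form.
    """
    if not isinstance(text, str):
        raise ParseError(f"age must be a string, got {type(text).__name__}")
    return AgeValue(text.strip())


def compare_age(a: AgeValue, b: AgeValue) -> int:
    """Three-way comparison of two ages by their total day count."""
    da, db = a.total_days(), b.total_days()
    return (da > db) - (da < db)


@dataclass
class Individual:
    """The subject of a phenopacket."""

    id: str
    sex: Sex = Sex.UNKNOWN_SEX
    time_at_last_encounter: AgeValue | None = None
    deceased: bool | None = None
    age_of_death: AgeValue | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("individual id must be nonempty")
        if self.deceased is False:
            # false and absent are the same wire value under default-omission
            self.deceased = None
        if self.age_of_death is not None and self.deceased is not True:
            raise ValidationError(
                f"individual {self.id!r}: age_of_death given but deceased is not true"
            )


@dataclass
class PhenotypicFeature:
    """One HPO annotation: a term asserted present or explicitly excluded."""

    type: OntologyClass
    excluded: bool = False
    onset: AgeValue | None = None

    def __post_init__(self) -> None:
        if not self.type.id.is_hpo():
            raise ValidationError(
                f"phenotypic feature id {self.type.id} is not an HP:nnnnnnn CURIE"
            )


@dataclass
class DiseaseDx:
    """A disease diagnosis encoded with an OMIM or Mondo identifier."""

    term: OntologyClass
    onset: AgeValue | None = None

    def __post_init__(self) -> None:
        if self.term.id.prefix not in ("OMIM", "MONDO"):
            raise ValidationError(
                f"disease id {self.term.id} must use the OMIM or MONDO prefix"
            )


@dataclass
class GeneContext:
    """Gene of the reported variant: HGNC id plus symbol."""

    hgnc_id: str
    symbol: str

    def __post_init__(self) -> None:
        if not HGNC_PATTERN.match(self.hgnc_id):
            raise ValidationError(f"not an HGNC id: {self.hgnc_id!r}")
        if not self.symbol:
            raise ValidationError("gene symbol must be nonempty")


class HgvsSyntax(enum.Enum):
    HGVS_C = "hgvs.c"
    HGVS_G = "hgvs.g"
    HGVS_P = "hgvs.p"


@dataclass
class Expression:
    """An HGVS expression for a variant (e.g. ``NM_003159.2:c.59G>A``)."""

    syntax: HgvsSyntax
    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise ValidationError("HGVS expression value must be nonempty")


# GENO ontology classes for allelic state; the id→label binding is a module
# table so alternative vocabularies can be swapped in.
ZYGOSITY: dict[str, OntologyClass] = {
    "heterozygous": OntologyClass(TermId("GENO:0000135"), "heterozygous"),
    "homozygous": OntologyClass(TermId("GENO:0000136"), "homozygous"),
    "hemizygous": OntologyClass(TermId("GENO:0000134"), "hemizygous"),
}


@dataclass
class VariationDescriptor:
    """A reported variant: either HGVS-described or qualitatively labeled.

    Structural variants known only from a qualitative report (e.g.
    "gene deletion" from a chromosomal microarray) carry ``sv_label`` and no
    HGVS expressions; sequence variants carry expressions and no label.
    Exactly one of the two modes is populated.
    """

    id: str
    gene: GeneContext
    allelic_state: OntologyClass
    expressions: list[Expression] = field(default_factory=list)
    sv_label: str | None = None

    def __post_init__(self) -> None:
        has_expr = bool(self.expressions)
        has_label = self.sv_label is not None and self.sv_label != ""
        if has_expr == has_label:
            raise ValidationError(
                f"variation descriptor {self.id!r} must have either HGVS "
                "expressions or an sv_label, not both and not neither"
            )
        if self.allelic_state.id.prefix != "GENO":
            raise ValidationError(
                f"allelic state of {self.id!r} must be a GENO class, "
                f"got {self.allelic_state.id}"
            )

    def allele_key(self) -> tuple[str, str]:
        """Identity used when counting unique alleles: (gene symbol, literal
        HGVS string or sv_label). No normalization is attempted."""
        if self.expressions:
            return (self.gene.symbol, self.expressions[0].value)
        return (self.gene.symbol, self.sv_label)  # type: ignore[return-value]


class InterpretationStatus(enum.Enum):
    CAUSATIVE = "CAUSATIVE"


class ProgressStatus(enum.Enum):
    SOLVED = "SOLVED"


@dataclass
class GenomicInterpretation:
    status: InterpretationStatus
    descriptor: VariationDescriptor


@dataclass
class Interpretation:
    """The genomic interpretation of a solved case.

    ``diagnosis_disease`` must name a disease present in the owning
    phenopacket's top-level disease list; that cross-reference is checked by
    the corpus validator, not here.
    """

    id: str
    diagnosis_disease: OntologyClass
    genomic_interpretations: list[GenomicInterpretation] = field(default_factory=list)
    progress_status: ProgressStatus = ProgressStatus.SOLVED

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("interpretation id must be nonempty")


@dataclass
class Resource:
    """A metadata entry resolving one CURIE prefix to an ontology release."""

    id: str
    name: str
    url: str
    version: str
    namespace_prefix: str
    iri_prefix: str


@dataclass
class MetaDataBlock:
    created: str
    created_by: str
    resources: list[Resource] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not self.created or not self.created_by:
            raise ValidationError("metadata must carry created and created_by")


@dataclass
class Phenopacket:
    """One individual's record: the unit of the corpus (one JSON file each)."""

    id: str
    subject: Individual
    phenotypic_features: list[PhenotypicFeature] = field(default_factory=list)
    diseases: list[DiseaseDx] = field(default_factory=list)
    interpretations: list[Interpretation] = field(default_factory=list)
    meta_data: MetaDataBlock | None = None

    def __post_init__(self) -> None:
        if not PHENOPACKET_ID_PATTERN.match(self.id):
            raise ValidationError(
                f"phenopacket id {self.id!r} does not match PMID_<digits>_<id>"
            )
        seen: set[tuple[str, bool]] = set()
        for f in self.phenotypic_features:
            key = (str(f.type.id), f.excluded)
            if key in seen:
                raise ValidationError(
                    f"phenopacket {self.id}: duplicate feature {key[0]} "
                    f"(excluded={f.excluded})"
                )
            seen.add(key)

    def present_features(self) -> list[PhenotypicFeature]:
        return [f for f in self.phenotypic_features if not f.excluded]

    def excluded_features(self) -> list[PhenotypicFeature]:
        return [f for f in self.phenotypic_features if f.excluded]


_SANITIZE_BAD = re.compile(r"[^A-Za-z0-9_.-]")
_UNDERSCORE_RUN = re.compile(r"_+")


def sanitize(raw: str) -> str:
    """Normalize an individual id for use inside a phenopacket id.

    Characters outside ``[A-Za-z0-9_.-]`` become ``_``; runs of ``_``
    collapse; leading/trailing ``_`` are stripped. The map is idempotent.
    An id that sanitizes to nothing becomes ``"individual"``.
    """
    out = _SANITIZE_BAD.sub("_", raw)
    out = _UNDERSCORE_RUN.sub("_", out).strip("_")
    return out or "individual"


def make_phenopacket_id(pmid: str, individual_id: str = "") -> str:
    """Build the corpus phenopacket id ``PMID_<pmid>_<individual>``.

    The PubMed id is prepended so the (PMID, individual) pair is unique
    across the corpus; publications that give no individual id use the word
    "individual".

    >>> make_phenopacket_id("24126608", "BAB3022")
    'PMID_24126608_BAB3022'
    """
    if not pmid or not pmid.isdigit():
        raise ArgumentError(f"pmid must be a nonempty digit string, got {pmid!r}")
    return f"PMID_{pmid}_{sanitize(individual_id)}"


def pmid_of(phenopacket_id: str) -> str | None:
    """Extract the PubMed id from a corpus phenopacket id, or None."""
    m = re.match(r"^PMID_(\d+)_", phenopacket_id)
    return m.group(1) if m else None


def build_sv_descriptor(
    gene: GeneContext,
    label: str,
    allelic_state: OntologyClass,
    descriptor_id: str = "sv",
) -> VariationDescriptor:
    """Build a descriptor for a structural variant known only qualitatively.

    Case reports often describe large deletions or duplications with a phrase
    like "gene deletion" rather than an HGVS expression; the phrase is kept
    verbatim as the descriptor label.
    """
    if not label:
        raise ArgumentError("sv label must be nonempty")
    return VariationDescriptor(
        id=descriptor_id, gene=gene, allelic_state=allelic_state, sv_label=label
    )
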