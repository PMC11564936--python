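"""Registry of metadata resources for the CURIE prefixes the corpus uses.

Every CURIE prefix appearing in a phenopacket must be resolvable through a
metadata resource entry (the schema's provenance principle); this table
supplies the standard entries so builders can attach them automatically.
"""

from __future__ import annotations

from .model import Resource

__all__ = ["KNOWN_RESOURCES", "resources_for"]

KNOWN_RESOURCES: dict[str, Resource] = {
    "HP": Resource(
        id="hp",
        name="human phenotype ontology",
        url="http://purl.obolibrary.org/obo/hp.owl",
        version="unversioned",
        namespace_prefix="HP",
        iri_prefix="http://purl.obolibrary.org/obo/HP_",
    ),
    "OMIM": Resource(
        id="omim",
        name="An Online Catalog of Human Genes and Genetic Disorders",
        url="https://www.omim.org",
        version="unversioned",
        namespace_prefix="OMIM",
        iri_prefix="https://www.omim.org/entry/",
    ),
    "MONDO": Resource(
        id="mondo",
        name="Mondo Disease Ontology",
        url="http://purl.obolibrary.org/obo/mondo.obo",
        version="unversioned",
        namespace_prefix="MONDO",
        iri_prefix="http://purl.obolibrary.org/obo/MONDO_",
    ),
    "GENO": Resource(
        id="geno",
        name="Genotype Ontology",
        url="http://purl.obolibrary.org/obo/geno.owl",
        version="unversioned",
        namespace_prefix="GENO",
        iri_prefix="http://purl.obolibrary.org/obo/GENO_",
    ),
    "HGNC": Resource(
        id="hgnc",
        name="HUGO Gene Nomenclature Committee",
        url="https://www.genenames.org",
        version="unversioned",
        namespace_prefix="HGNC",
        iri_prefix="https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/HGNC:",
    ),
}


def resources_for(prefixes: list[str], version: str | None = None) -> list[Resource]:
    """Resource entries for the given prefixes, in the given order.

    Unknown prefixes get a stub entry so the provenance invariant still
    holds; *version* overrides the recorded ontology version on all entries.
    """
    out = []
    for prefix in prefixes:
        base = KNOWN_RESOURCES.get(prefix)
        if base is None:
            base = Resource(
                id=prefix.lower(),
                name=f"{prefix} (unregistered)",
                url=f"https://bioregistry.io/{prefix.lower()}",
                version="unversioned",
                namespace_prefix=prefix,
                iri_prefix=f"https://bioregistry.io/{prefix.lower()}:",
            )
        if version is not None:
            base = Resource(
                base.id, base.name, base.url, version, base.namespace_prefix,
                base.iri_prefix,
            )
        out.append(base)
    return out
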