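"""Minimal ontology support: an is_a DAG of terms with subsumption queries.

Quality control of phenotype annotations needs exactly one reasoning
primitive — the ancestor closure over ``is_a`` edges. An observed term
implies all of its ancestors; an excluded term implies exclusion of all of
its descendants. This module loads an obographs-style JSON subset into a
directed acyclic graph and answers those closure queries.

Only ``is_a``/``subClassOf`` edges are honored; every other predicate is
counted and ignored. Obsolete terms load normally and are flagged; using one
in a phenopacket is a validation finding, not a load error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import FormatError, LookupError_, StructuralError
from .model import TermId

logger = logging.getLogger(__name__)

__all__ = ["OntologyTerm", "OntologyGraph", "load_ontology", "VIRTUAL_ROOT"]

#: Synthesized super-root used when a file contains several parentless terms.
#: Internal only: never serialized, never a legal annotation.
VIRTUAL_ROOT = TermId("OWL:Thing")

_ISA_PREDICATES = {"is_a", "subClassOf", "rdfs:subClassOf"}


@dataclass
class OntologyTerm:
    id: TermId
    label: str
    obsolete: bool = False
    parents: set[TermId] = field(default_factory=set)


class OntologyGraph:
    """An is_a hierarchy with O(edges) ancestor/descendant closure.

    Internally a :class:`networkx.DiGraph` with child→parent edges, so the
    ancestor closure of a term is graph reachability from it.
    """

    def __init__(self, terms: dict[TermId, OntologyTerm], root: TermId):
        self.terms = terms
        self.root = root
        self._g = nx.DiGraph()
        self._g.add_nodes_from(terms)
        for t in terms.values():
            for p in t.parents:
                if p == t.id:
                    raise StructuralError(f"term {t.id} is its own parent")
                if p not in terms:
                    raise StructuralError(f"term {t.id} has unknown parent {p}")
                self._g.add_edge(t.id, p)
        try:
            cycle = nx.find_cycle(self._g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise StructuralError(
                f"is_a hierarchy contains a cycle through {cycle[0][0]}"
            )

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        n = len(self.terms)
        return n - 1 if self.root == VIRTUAL_ROOT else n

    def term(self, t: str) -> OntologyTerm:
        try:
            return self.terms[TermId(t)]
        except KeyError:
            raise LookupError_(f"term {t} is not in the ontology") from None

    def label_of(self, t: str) -> str:
        return self.term(t).label

    def is_obsolete(self, t: str) -> bool:
        return self.term(t).obsolete

    def ancestors(self, t: str, include_self: bool = False) -> set[TermId]:
        """Transitive closure over parent edges, optionally including *t*."""
        t = TermId(t)
        if t not in self.terms:
            raise LookupError_(f"term {t} is not in the ontology")
        anc = set(nx.descendants(self._g, t))  # child→parent edges: reachability
        anc.discard(VIRTUAL_ROOT)
        if include_self:
            anc.add(t)
        return anc

    def descendants(self, t: str, include_self: bool = False) -> set[TermId]:
        t = TermId(t)
        if t not in self.terms:
            raise LookupError_(f"term {t} is not in the ontology")
        desc = set(nx.ancestors(self._g, t))
        if include_self:
            desc.add(t)
        return desc

    def is_ancestor(self, a: str, d: str) -> bool:
        """True iff *a* is a proper ancestor of *d* via is_a edges."""
        a = TermId(a)
        if a not in self.terms:
            raise LookupError_(f"term {a} is not in the ontology")
        return a in self.ancestors(d, include_self=False)


def _curie_from_iri(raw: str) -> TermId:
    """Convert an OBO-style IRI (``.../HP_0001250``) to a CURIE; CURIEs pass
    through unchanged."""
    if "://" in raw:
        tail = raw.rstrip("/").rsplit("/", 1)[-1]
        if "_" in tail:
            prefix, _, local = tail.partition("_")
            return TermId(f"{prefix}:{local}")
        return TermId(tail)
    return TermId(raw)


def load_ontology(path: str | Path, dialect: str = "obographs-json-subset") -> OntologyGraph:
    """Load an ontology from an obographs-style JSON file.

    The subset read is ``graphs[0].nodes[].{id, lbl, meta.deprecated}`` and
    ``graphs[0].edges[].{sub, pred, obj}``. Node ids may be IRIs or CURIEs.
    If several non-obsolete terms are parentless, a virtual super-root binds
    them so the ancestor closure stays total.
    """
    if dialect != "obographs-json-subset":
        raise FormatError(f"unsupported ontology dialect: {dialect}")
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse ontology file {path}: {exc}") from exc

    try:
        graph = doc["graphs"][0]
        raw_nodes = graph["nodes"]
        raw_edges = graph.get("edges", [])
    except (KeyError, IndexError, TypeError) as exc:
        raise FormatError(
            f"{path} is not an obographs document (missing graphs[0].nodes)"
        ) from exc

    terms: dict[TermId, OntologyTerm] = {}
    for node in raw_nodes:
        if "id" not in node:
            raise FormatError(f"{path}: node without id")
        tid = _curie_from_iri(node["id"])
        meta = node.get("meta") or {}
        terms[tid] = OntologyTerm(
            id=tid,
            label=node.get("lbl", str(tid)),
            obsolete=bool(meta.get("deprecated", False)),
        )

    ignored = 0
    for edge in raw_edges:
        pred = edge.get("pred", "")
        if pred not in _ISA_PREDICATES:
            ignored += 1
            continue
        child = _curie_from_iri(edge["sub"])
        parent = _curie_from_iri(edge["obj"])
        if child not in terms or parent not in terms:
            raise FormatError(f"{path}: edge references unknown term {child}->{parent}")
        terms[child].parents.add(parent)
    if ignored:
        logger.info("ignored %d non-is_a edges in %s", ignored, path)

    roots = [t.id for t in terms.values() if not t.parents and not t.obsolete]
    if not roots:
        obs_roots = [t.id for t in terms.values() if not t.parents]
        if not obs_roots:
            raise StructuralError(f"{path}: no parentless term; hierarchy is cyclic")
        roots = obs_roots
    if len(roots) == 1:
        root = roots[0]
    else:
        terms[VIRTUAL_ROOT] = OntologyTerm(id=VIRTUAL_ROOT, label="virtual root")
        for r in (t.id for t in terms.values() if not t.parents and t.id != VIRTUAL_ROOT):
            terms[r].parents.add(VIRTUAL_ROOT)
        root = VIRTUAL_ROOT

    return OntologyGraph(terms, root)
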