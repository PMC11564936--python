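"""Shared fixtures: toy ontologies, random DAGs, and a reachability oracle
that is independent of the graph implementation under test."""

from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import settings

from phenocurate.model import TermId
from phenocurate.ontology import OntologyGraph, OntologyTerm
from phenocurate.simulate import GeneratorConfig, generate_corpus, generate_ontology

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_graph(parents: dict[str, list[str]], root: str,
               obsolete: set[str] | None = None) -> OntologyGraph:
    """Build an OntologyGraph directly from a parent map."""
    obsolete = obsolete or set()
    terms = {
        TermId(t): OntologyTerm(
            id=TermId(t),
            label=f"term {t}",
            obsolete=t in obsolete,
            parents={TermId(p) for p in ps},
        )
        for t, ps in parents.items()
    }
    return OntologyGraph(terms, TermId(root))


def brute_force_ancestors(parents: dict[str, list[str]], t: str) -> set[str]:
    """Exhaustive parent-path enumeration; the independent closure oracle."""
    found: set[str] = set()

    def walk(node: str) -> None:
        for p in parents[node]:
            found.add(p)
            walk(p)  # revisits are fine on a DAG this small

    walk(t)
    return found


def random_dag(rng: np.random.Generator, n_nodes: int) -> dict[str, list[str]]:
    """Random rooted DAG as a parent map; node 0 is the root. Every non-root
    node gets 1-3 parents among earlier nodes, so the root is reachable."""
    names = [f"HP:{9100000 + i}" for i in range(n_nodes)]
    parents: dict[str, list[str]] = {names[0]: []}
    for i in range(1, n_nodes):
        n_par = int(rng.integers(1, min(3, i) + 1))
        chosen = rng.choice(i, size=n_par, replace=False)
        parents[names[i]] = [names[int(c)] for c in sorted(chosen)]
    return parents


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """root ← A ← B is_a chain."""
    return make_graph(
        {"HP:9000001": [], "HP:9000002": ["HP:9000001"], "HP:9000003": ["HP:9000002"]},
        root="HP:9000001",
    )


@pytest.fixture
def chain_file(tmp_path):
    """The same chain as an obographs JSON file."""
    doc = {
        "graphs": [
            {
                "nodes": [
                    {"id": "HP:9000001", "lbl": "root"},
                    {"id": "HP:9000002", "lbl": "A"},
                    {"id": "HP:9000003", "lbl": "B"},
                ],
                "edges": [
                    {"sub": "HP:9000002", "pred": "is_a", "obj": "HP:9000001"},
                    {"sub": "HP:9000003", "pred": "is_a", "obj": "HP:9000002"},
                ],
            }
        ]
    }
    path = tmp_path / "chain.json"
    path.write_text(json.dumps(doc))
    return path


@pytest.fixture(scope="session")
def small_corpus():
    """A modest rule-clean corpus shared by read-only tests."""
    cfg = GeneratorConfig(seed=11, n_genes=6, mean_cohort_size=8)
    g = generate_ontology(cfg)
    packets, truth = generate_corpus(cfg, g)
    return g, packets, truth
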