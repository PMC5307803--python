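"""Shared fixtures: tiny hand-checkable ontologies and brute-force oracles."""

from __future__ import annotations

import io

import networkx as nx
import numpy as np
import pytest

from ontosim import (
    AnnotationCorpus,
    OntologyGraph,
    TermInfo,
    compute_intrinsic_ic,
    parse_obo,
)

# Five-class toy ontology: R is the root, A and B its children, C and D
# children of A.  Small enough that every similarity value can be done by
# hand: IC(R)=0, IC(A)=1-ln3/ln5, IC(B)=IC(C)=IC(D)=1.
T1_OBO = """\
format-version: 1.2

[Term]
id: R
name: root

[Term]
id: A
name: mid
is_a: R

[Term]
id: B
name: leaf b
is_a: R

[Term]
id: C
name: leaf c
is_a: A

[Term]
id: D
name: leaf d
is_a: A
"""


@pytest.fixture(scope="session")
def t1():
    return parse_obo(io.StringIO(T1_OBO))


@pytest.fixture(scope="session")
def t1_ic(t1):
    return compute_intrinsic_ic(t1)


@pytest.fixture(scope="session")
def diamond():
    # X is_a A, X is_a B, A is_a R, B is_a R: multi-path descendants
    terms = {c: TermInfo() for c in "RABX"}
    edges = [("A", "R", "is_a"), ("B", "R", "is_a"), ("X", "A", "is_a"), ("X", "B", "is_a")]
    return OntologyGraph(terms, edges)


def random_dag(n: int, max_parents: int, seed: int) -> OntologyGraph:
    """Independent uniform-attachment DAG builder used as a test oracle input."""
    rng = np.random.default_rng(seed)
    ids = [f"N{i}" for i in range(n)]
    terms = {c: TermInfo() for c in ids}
    edges = []
    for i in range(1, n):
        k = min(int(rng.integers(1, max_parents + 1)), i)
        for p in rng.choice(i, size=k, replace=False):
            edges.append((ids[i], ids[int(p)], "is_a"))
    return OntologyGraph(terms, edges)


def closure_oracle(g: OntologyGraph) -> dict[str, frozenset[str]]:
    """Reflexive transitive closure by boolean-matrix iteration."""
    nodes = g.active_classes
    idx = {c: i for i, c in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for child, parent, _rel in g.edges:
        reach[idx[child], idx[parent]] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    return {c: frozenset(nodes[j] for j in np.flatnonzero(reach[idx[c]])) for c in nodes}


def depth_oracle(g: OntologyGraph) -> dict[str, int]:
    """Shortest path to any root via networkx on the child->parent digraph."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.active_classes)
    dg.add_edges_from((child, parent) for child, parent, _ in g.edges)
    out = {}
    for c in g.active_classes:
        out[c] = min(
            nx.shortest_path_length(dg, c, r)
            for r in g.roots
            if nx.has_path(dg, c, r)
        )
    return out


@pytest.fixture(scope="session")
def t1_corpus():
    return AnnotationCorpus({"e1": {"C"}, "e2": {"D"}, "e3": {"C", "B"}})
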