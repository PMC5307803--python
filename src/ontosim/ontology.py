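"""Ontology graphs, structural statistics and intrinsic information content.

An ontology (GO, HPO, MPO, ...) is reduced to a directed acyclic graph whose
nodes are classes and whose edges point from a child class to each of its
parents via a configurable set of relations (``is_a`` and/or ``part_of``).
Obsolete classes are parsed but take part in no edge, no closure and no
normalization constant.

Intrinsic information content (IC) is derived from topology alone, in the
descendant-counting style of Seco et al.: a class subsuming many others is
uninformative (IC 0 at a root), a leaf is maximally informative (IC 1).
"""

from __future__ import annotations

import contextlib
import gzip
import io
import logging
import math
import os
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx
import obonet

__all__ = [
    "TermInfo",
    "OntologyGraph",
    "ICTable",
    "parse_obo",
    "ancestor_closure",
    "class_depth",
    "descendant_count",
    "compute_intrinsic_ic",
    "write_obo",
    "DEFAULT_RELATIONS",
]

#: Parent-edge relations used for the traversal graph unless overridden.
DEFAULT_RELATIONS: frozenset[str] = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class TermInfo:
    """Static per-class metadata carried alongside the graph structure."""

    name: str = ""
    namespace: str = ""
    obsolete: bool = False


class OntologyGraph:
    """A DAG of ontology classes with child-to-parent typed edges.

    Parameters
    ----------
    terms:
        Mapping of class id to :class:`TermInfo` (obsolete classes included).
    edges:
        Iterable of ``(child, parent, relation)`` triples.  Edges touching an
        obsolete endpoint are dropped; the surviving graph must be acyclic.
    """

    def __init__(
        self,
        terms: dict[str, TermInfo],
        edges: Iterable[tuple[str, str, str]],
    ) -> None:
        self.terms: dict[str, TermInfo] = dict(terms)
        self._parents = nx.DiGraph()
        for cid, info in self.terms.items():
            if not info.obsolete:
                self._parents.add_node(cid)
        kept: list[tuple[str, str, str]] = []
        for child, parent, rel in edges:
            if child not in self.terms or parent not in self.terms:
                raise KeyError(f"edge references unknown class: {child} -> {parent}")
            if self.terms[child].obsolete or self.terms[parent].obsolete:
                continue
            self._parents.add_edge(child, parent, relation=rel)
            kept.append((child, parent, rel))
        self.edges: tuple[tuple[str, str, str], ...] = tuple(kept)
        if not nx.is_directed_acyclic_graph(self._parents):
            cycle = nx.find_cycle(self._parents)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"ontology contains a cycle: {path}")
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._depths: dict[str, int] | None = None
        self._long_depths: dict[str, int] | None = None
        self._desc_counts: dict[str, int] | None = None
        self._component_of: dict[str, int] | None = None

    # ------------------------------------------------------------------ basic

    @property
    def n_classes(self) -> int:
        return len(self.terms)

    @property
    def n_obsolete(self) -> int:
        return sum(1 for t in self.terms.values() if t.obsolete)

    @property
    def active_classes(self) -> list[str]:
        """Non-obsolete class ids, sorted for determinism."""
        return sorted(self._parents.nodes)

    @property
    def roots(self) -> list[str]:
        return sorted(c for c in self._parents.nodes if self._parents.out_degree(c) == 0)

    def is_active(self, c: str) -> bool:
        return c in self._parents

    def _require_active(self, c: str) -> None:
        if c not in self.terms:
            raise KeyError(f"unknown ontology class: {c}")
        if self.terms[c].obsolete:
            raise ValueError(f"class is obsolete: {c}")

    def parents_of(self, c: str) -> list[str]:
        self._require_active(c)
        return sorted(self._parents.successors(c))

    def children_of(self, c: str) -> list[str]:
        self._require_active(c)
        return sorted(self._parents.predecessors(c))

    # -------------------------------------------------------------- structure

    def ancestors(self, c: str) -> frozenset[str]:
        """Reflexive transitive closure of ``c`` over parent edges."""
        self._require_active(c)
        cached = self._anc_cache.get(c)
        if cached is not None:
            return cached
        seen = {c}
        stack = [c]
        while stack:
            for p in self._parents.successors(stack.pop()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        result = frozenset(seen)
        self._anc_cache[c] = result
        return result

    def depths(self, longest: bool = False) -> dict[str, int]:
        """Depth of every active class.

        Default depth is the shortest parent-edge path to any root
        (``depth(root) == 0``); ``longest=True`` switches to the longest
        such path.
        """
        if not longest:
            if self._depths is None:
                self._depths = self._shortest_depths()
            return self._depths
        if self._long_depths is None:
            self._long_depths = self._longest_depths()
        return self._long_depths

    def _shortest_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {r: 0 for r in self.roots}
        queue = deque(self.roots)
        while queue:
            node = queue.popleft()
            for child in self._parents.predecessors(node):
                if child not in depth:
                    depth[child] = depth[node] + 1
                    queue.append(child)
        return depth

    def _longest_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        for node in nx.topological_sort(self._parents.reverse(copy=False)):
            preds = list(self._parents.successors(node))
            depth[node] = 0 if not preds else 1 + max(depth[p] for p in preds)
        return depth

    def descendant_counts(self) -> dict[str, int]:
        """Number of distinct proper descendants for every active class."""
        if self._desc_counts is None:
            counts: Counter[str] = Counter()
            for c in self._parents.nodes:
                counts.update(self.ancestors(c))
            # each class is in its own closure; subtract the reflexive hit
            self._desc_counts = {c: counts[c] - 1 for c in self._parents.nodes}
        return self._desc_counts

    def components(self) -> dict[str, int]:
        """Weakly connected component index of every active class."""
        if self._component_of is None:
            comp: dict[str, int] = {}
            for i, nodes in enumerate(
                sorted(nx.weakly_connected_components(self._parents), key=min)
            ):
                for c in nodes:
                    comp[c] = i
            self._component_of = comp
        return self._component_of

    def component_sizes(self) -> dict[int, int]:
        return Counter(self.components().values())

    def classes_at_depth(self, d: int, longest: bool = False) -> list[str]:
        return sorted(c for c, v in self.depths(longest).items() if v == d)


# ---------------------------------------------------------------------- ops


def ancestor_closure(g: OntologyGraph, c: str) -> frozenset[str]:
    """Reflexive set of all classes reachable from ``c`` via parent edges."""
    return g.ancestors(c)


def class_depth(g: OntologyGraph, c: str, longest: bool = False) -> int:
    """Length of the shortest (default) parent-edge path from ``c`` to a root."""
    g._require_active(c)
    depths = g.depths(longest)
    if c not in depths:
        raise ValueError(f"class {c} is disconnected from every root")
    return depths[c]


def descendant_count(g: OntologyGraph, c: str) -> int:
    g._require_active(c)
    return g.descendant_counts()[c]


# ------------------------------------------------------------------ parsing


def _open_text(source: str | os.PathLike | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = os.fspath(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _validate_stanza_lines(text: str) -> None:
    """Cheap structural check so malformed stanza lines carry a line number."""
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line in ("[Term]", "[Typedef]", "[Instance]")
            if not (line.startswith("[") and line.endswith("]")):
                raise ValueError(f"malformed stanza header at line {lineno}: {raw!r}")
            continue
        if in_term and ":" not in line:
            raise ValueError(f"malformed tag-value line at line {lineno}: {raw!r}")


@contextlib.contextmanager
def _quiet_header_warning():
    """Drop obonet's warning about minimal headers (common in toy files)."""

    class _Filter(logging.Filter):
        def filter(self, record: logging.LogRecord) -> bool:
            return "ontology keys are both missing" not in record.getMessage()

    root = logging.getLogger()
    f = _Filter()
    root.addFilter(f)
    try:
        yield
    finally:
        root.removeFilter(f)


def parse_obo(
    source: str | os.PathLike | IO[str],
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Parse an OBO 1.2 flat file (gzip-transparent) into an :class:`OntologyGraph`.

    Only ``id``, ``name``, ``namespace``, ``is_a``, ``relationship`` and
    ``is_obsolete`` tags are consumed; all other tags are ignored.  Edges are
    kept only for the requested ``relations`` and only between non-obsolete
    classes.  A cyclic structure raises :class:`ValueError` naming one cycle.
    """
    relset = frozenset(relations)
    if not relset:
        raise ValueError("relations must be a non-empty set")
    unknown = relset - {"is_a", "part_of"}
    if unknown:
        raise ValueError(f"unsupported relations: {sorted(unknown)}")
    handle = _open_text(source)
    text = handle.read()
    _validate_stanza_lines(text)
    with _quiet_header_warning():
        multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    terms: dict[str, TermInfo] = {}
    for cid, data in multigraph.nodes(data=True):
        terms[cid] = TermInfo(
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        )
    edges = [
        (child, parent, rel)
        for child, parent, rel in multigraph.edges(keys=True)
        if rel in relset
    ]
    return OntologyGraph(terms, edges)


def write_obo(g: OntologyGraph, path: str | os.PathLike) -> None:
    """Serialize a graph back to minimal OBO 1.2 (ids, names, edges, obsolete)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        by_child: dict[str, list[tuple[str, str]]] = {}
        for child, parent, rel in g.edges:
            by_child.setdefault(child, []).append((rel, parent))
        for cid in sorted(g.terms):
            info = g.terms[cid]
            fh.write(f"\n[Term]\nid: {cid}\n")
            if info.name:
                fh.write(f"name: {info.name}\n")
            if info.namespace:
                fh.write(f"namespace: {info.namespace}\n")
            for rel, parent in sorted(by_child.get(cid, [])):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            if info.obsolete:
                fh.write("is_obsolete: true\n")


# ----------------------------------------------------------------------- IC


@dataclass
class ICTable:
    """Per-class intrinsic information content and its ingredients.

    ``ic`` lies in [0, 1]: 0 at the root of each connected component, 1 at
    leaves.  ``p`` is the topological occurrence proxy
    ``(descendants + 1) / N`` with N the number of non-obsolete classes in the
    class's component, so ``p(root) == 1``.
    """

    ic: dict[str, float]
    p: dict[str, float]
    descendant_count: dict[str, int]
    component_n: dict[str, int]
    formula: str = "seco"

    @property
    def max_ic(self) -> float:
        return max(self.ic.values(), default=0.0)

    def __getitem__(self, c: str) -> float:
        return self.ic[c]


def compute_intrinsic_ic(g: OntologyGraph, formula: str = "seco") -> ICTable:
    """Compute intrinsic IC for every non-obsolete class.

    The default ``seco`` formula is
    ``IC(c) = 1 - log(desc(c) + 1) / log(N)`` with ``desc(c)`` the number of
    proper descendants of ``c`` and ``N`` the class count of its component.
    ``sanchez`` offers the leaves-over-subsumers alternative, normalized to
    [0, 1] per component; the single-class-component IC is 0 in both.
    """
    if formula not in ("seco", "sanchez"):
        raise ValueError(f"unknown IC formula: {formula}")
    counts = g.descendant_counts()
    comp = g.components()
    comp_sizes = g.component_sizes()
    ic: dict[str, float] = {}
    p: dict[str, float] = {}
    component_n = {c: comp_sizes[comp[c]] for c in comp}
    for c, n in component_n.items():
        p[c] = (counts[c] + 1) / n
    if formula == "seco":
        for c, n in component_n.items():
            ic[c] = 0.0 if n == 1 else 1.0 - math.log(counts[c] + 1) / math.log(n)
    else:
        ic = _sanchez_ic(g, comp, comp_sizes)
    return ICTable(ic=ic, p=p, descendant_count=dict(counts), component_n=component_n, formula=formula)


def _sanchez_ic(
    g: OntologyGraph, comp: dict[str, int], comp_sizes: dict[int, int]
) -> dict[str, float]:
    leaves = {c for c in comp if not g.children_of(c)}
    leaf_desc: Counter[str] = Counter()
    for leaf in leaves:
        leaf_desc.update(g.ancestors(leaf))
    comp_leaves = Counter(comp[leaf] for leaf in leaves)
    ic: dict[str, float] = {}
    for c in comp:
        n_leaves = comp_leaves[comp[c]]
        if comp_sizes[comp[c]] == 1:
            ic[c] = 0.0
            continue
        subsumers = len(g.ancestors(c))
        own_leaves = leaf_desc[c] if c not in leaves else 1
        raw = -math.log((own_leaves / subsumers + 1) / (n_leaves + 1))
        ic[c] = raw / math.log(n_leaves + 1)
    return ic
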