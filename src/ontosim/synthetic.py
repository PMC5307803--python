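"""Synthetic ontologies, annotation corpora and interaction networks.

Everything the bias analyses need can be generated here without any
download: a random-DAG toy ontology standing in for GO/HPO, corpora whose
entities have a controlled annotation size (the design is 100 entities per
size 1..55) or a controlled annotation-class depth (100 entities per depth,
GO reaching depth 17), a size-preserving randomization of any corpus, and
interaction networks with a tunable annotation-size/degree confounder.

All generators are deterministic for a given integer seed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .corpus import AnnotationCorpus
from .ontology import OntologyGraph, TermInfo

__all__ = [
    "generate_random_dag",
    "generate_layered_dag",
    "annotate_by_size",
    "annotate_by_depth",
    "shuffle_annotations",
    "random_interactions",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_random_dag(
    n_classes: int, max_parents: int = 3, seed: int | np.random.Generator = 0
) -> OntologyGraph:
    """Random single-rooted DAG with ``is_a`` edges.

    Class ``i`` (ids ``T:0000001`` ...) draws 1..``max_parents`` distinct
    parents uniformly among earlier classes, so the graph is acyclic by
    construction and every class reaches the single root.
    """
    if n_classes < 1 or max_parents < 1:
        raise ValueError("n_classes and max_parents must be >= 1")
    rng = _rng(seed)
    ids = [f"T:{i + 1:07d}" for i in range(n_classes)]
    terms = {cid: TermInfo(name=f"class {i}") for i, cid in enumerate(ids)}
    edges: list[tuple[str, str, str]] = []
    for i in range(1, n_classes):
        k = min(int(rng.integers(1, max_parents + 1)), i)
        parents = rng.choice(i, size=k, replace=False)
        for p in sorted(parents):
            edges.append((ids[i], ids[p], "is_a"))
    return OntologyGraph(terms, edges)


def generate_layered_dag(
    n_classes: int,
    branching: int = 3,
    extra_parent_prob: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> OntologyGraph:
    """Random layered DAG emulating the closure structure of bio-ontologies.

    Classes fill depth strata of geometrically growing capacity (stratum d
    holds up to ``branching**d`` classes); each class draws one parent
    uniformly from the stratum above and, with probability
    ``extra_parent_prob``, a second distinct parent from the same stratum.
    Because extra parents sit at the primary parent's depth — as secondary
    parents usually do in GO — ancestor closures stay compact (roughly the
    class depth plus a few), unlike uniform attachment over all earlier
    classes, whose closures engulf a large fraction of a small ontology and
    saturate set-overlap measures.  Depth strata are exact, which also gives
    the depth-controlled corpora well-populated groups.
    """
    if n_classes < 1 or branching < 2:
        raise ValueError("need n_classes >= 1 and branching >= 2")
    if not 0.0 <= extra_parent_prob <= 1.0:
        raise ValueError("extra_parent_prob must be a probability")
    rng = _rng(seed)
    ids = [f"T:{i + 1:07d}" for i in range(n_classes)]
    terms = {cid: TermInfo(name=f"class {i}") for i, cid in enumerate(ids)}
    edges: list[tuple[str, str, str]] = []
    previous = [0]
    capacity = 1
    i = 1
    while i < n_classes:
        capacity *= branching
        stratum: list[int] = []
        while i < n_classes and len(stratum) < capacity:
            p = int(rng.choice(previous))
            edges.append((ids[i], ids[p], "is_a"))
            if len(previous) > 1 and rng.random() < extra_parent_prob:
                extra = int(rng.choice([x for x in previous if x != p]))
                edges.append((ids[i], ids[extra], "is_a"))
            stratum.append(i)
            i += 1
        previous = stratum
    return OntologyGraph(terms, edges)


def annotate_by_size(
    g: OntologyGraph,
    sizes: Sequence[int],
    n_per_group: int,
    seed: int | np.random.Generator = 0,
) -> AnnotationCorpus:
    """Corpus with ``n_per_group`` entities per requested annotation size.

    Each entity draws its classes uniformly, without replacement, from all
    non-obsolete classes of the ontology (all components pooled).
    """
    rng = _rng(seed)
    universe = np.array(g.active_classes)
    if max(sizes) > len(universe):
        raise ValueError(
            f"requested size {max(sizes)} exceeds the {len(universe)}-class universe"
        )
    annotations: dict[str, frozenset[str]] = {}
    labels: dict[str, int] = {}
    for s in sizes:
        for j in range(n_per_group):
            entity = f"S{s:03d}_{j:04d}"
            picked = rng.choice(universe, size=s, replace=False)
            annotations[entity] = frozenset(picked.tolist())
            labels[entity] = int(s)
    return AnnotationCorpus(
        annotations,
        grouping="size",
        group_labels=labels,
        provenance={"generator": "annotate_by_size", "sizes": list(map(int, sizes)),
                    "n_per_group": int(n_per_group)},
    )


def annotate_by_depth(
    g: OntologyGraph,
    depths: Sequence[int],
    n_per_group: int,
    size_per_entity: int = 10,
    seed: int | np.random.Generator = 0,
) -> AnnotationCorpus:
    """Corpus whose entities draw all classes from one fixed depth.

    Depth is the shortest parent-path to a root.  If a depth stratum holds
    fewer classes than ``size_per_entity``, sampling falls back to with
    replacement followed by deduplication (flagged in provenance), so the
    effective annotation size may shrink for thin strata.
    """
    rng = _rng(seed)
    strata = {d: np.array(g.classes_at_depth(d)) for d in depths}
    empty = [d for d, classes in strata.items() if classes.size == 0]
    if empty:
        raise ValueError(f"no classes at depth {empty[0]}")
    annotations: dict[str, frozenset[str]] = {}
    labels: dict[str, int] = {}
    deduped = False
    for d in depths:
        pool = strata[d]
        for j in range(n_per_group):
            entity = f"D{d:03d}_{j:04d}"
            if size_per_entity <= pool.size:
                picked = rng.choice(pool, size=size_per_entity, replace=False)
            else:
                picked = rng.choice(pool, size=size_per_entity, replace=True)
                deduped = True
            annotations[entity] = frozenset(picked.tolist())
            labels[entity] = int(d)
    return AnnotationCorpus(
        annotations,
        grouping="depth",
        group_labels=labels,
        provenance={
            "generator": "annotate_by_depth",
            "depths": list(map(int, depths)),
            "n_per_group": int(n_per_group),
            "size_per_entity": int(size_per_entity),
            "sampled_with_replacement": deduped,
        },
    )


def shuffle_annotations(
    corpus: AnnotationCorpus,
    g: OntologyGraph,
    seed: int | np.random.Generator = 0,
) -> AnnotationCorpus:
    """Replace every entity's classes by random ones, preserving its count.

    The randomized corpus keeps the exact per-entity annotation size (each
    new set is drawn without replacement from all non-obsolete classes), so
    the annotation-size histogram is bit-identical while all biological
    content is destroyed.  This is the null model behind the bias audit.
    """
    rng = _rng(seed)
    universe = np.array(g.active_classes)
    annotations: dict[str, frozenset[str]] = {}
    for entity in corpus.entity_ids:
        k = len(corpus[entity])
        annotations[entity] = frozenset(rng.choice(universe, size=k, replace=False).tolist())
    return AnnotationCorpus(
        annotations,
        grouping=corpus.grouping,
        group_labels=corpus.group_labels,
        provenance={**corpus.provenance, "shuffled": True},
    )


def random_interactions(
    corpus: AnnotationCorpus,
    n_edges: int,
    size_bias: float = 0.0,
    hub_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Random interaction network over the corpus entities.

    Endpoints are sampled with probability proportional to
    ``size ** size_bias * lognormal(0, hub_sigma)``: with both parameters 0
    the network is uniform and degree is independent of annotation size;
    ``size_bias > 0`` couples degree to annotation size (the study-more/
    annotate-more/interact-more confounder of curated interactomes) and
    ``hub_sigma > 0`` adds the heavy-tailed hub structure real interactomes
    show, which attenuates the size/degree Pearson correlation while
    concentrating interactions on few entities.
    """
    from .association import InteractionSet  # local import to avoid a cycle

    rng = _rng(seed)
    entities = corpus.entity_ids
    sizes = np.array([len(corpus[e]) for e in entities], dtype=float)
    weights = sizes**size_bias
    if hub_sigma > 0.0:
        weights = weights * rng.lognormal(0.0, hub_sigma, len(entities))
    prob = weights / weights.sum()
    max_edges = len(entities) * (len(entities) - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"cannot place {n_edges} edges among {len(entities)} entities")
    pairs: set[tuple[str, str]] = set()
    while len(pairs) < n_edges:
        draw = rng.choice(len(entities), size=2, replace=False, p=prob)
        a, b = entities[draw[0]], entities[draw[1]]
        pairs.add((a, b) if a < b else (b, a))
    return InteractionSet(frozenset(pairs))
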