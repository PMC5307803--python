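"""Semantic similarity between ontology classes and between annotated entities.

Two families are implemented, both driven by intrinsic information content:

* pairwise class-class measures — Resnik (IC of the most informative common
  ancestor, MICA), Lin, Jiang-Conrath (transformed to a similarity via
  ``1/(1+d)``) and Schlicker's relevance measure — lifted to entities by a
  mixing strategy (Average, Best Match Average, Max) over the direct classes;
* groupwise set measures on the ancestor-closed (extended) annotation sets —
  simGIC (IC-weighted Jaccard), UI (unweighted Jaccard) and NTO (overlap
  normalized by the smaller set).

``similarity_matrix`` evaluates a full entity-by-entity matrix with
vectorized NumPy kernels; the scalar operations above it stay the readable
single-pair reference and the two paths are interchangeable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus import AnnotationCorpus, AnnotationSet
from .ontology import ICTable, OntologyGraph

__all__ = [
    "MeasureSpec",
    "SimilarityMatrix",
    "PAIRWISE_MEASURES",
    "GROUPWISE_MEASURES",
    "STRATEGIES",
    "mica",
    "pairwise_similarity",
    "combine_pairwise",
    "groupwise_similarity",
    "entity_similarity",
    "similarity_matrix",
    "write_matrix_tsv",
    "write_matrix_long_tsv",
]

PAIRWISE_MEASURES = ("Resnik", "Lin", "JiangConrath", "Schlicker")
GROUPWISE_MEASURES = ("GIC", "UI", "NTO")
STRATEGIES = ("Average", "BMA", "Max")

_NAME_ALIASES = {
    "resnik": "Resnik",
    "lin": "Lin",
    "jiangconrath": "JiangConrath",
    "jiang-conrath": "JiangConrath",
    "jc": "JiangConrath",
    "schlicker": "Schlicker",
    "gic": "GIC",
    "simgic": "GIC",
    "ui": "UI",
    "nto": "NTO",
}
_STRATEGY_ALIASES = {
    "average": "Average",
    "avg": "Average",
    "mean": "Average",
    "bma": "BMA",
    "max": "Max",
}


@dataclass(frozen=True)
class MeasureSpec:
    """A fully specified similarity measure.

    ``strategy`` is required for pairwise measures and forbidden for
    groupwise ones.
    """

    name: str
    strategy: str | None = None

    def __post_init__(self) -> None:
        if self.name in GROUPWISE_MEASURES:
            if self.strategy is not None:
                raise ValueError(f"groupwise measure {self.name} takes no strategy")
        elif self.name in PAIRWISE_MEASURES:
            if self.strategy not in STRATEGIES:
                raise ValueError(
                    f"pairwise measure {self.name} needs a strategy in {STRATEGIES}"
                )
        else:
            raise ValueError(f"unknown measure: {self.name}")

    @property
    def kind(self) -> str:
        return "groupwise" if self.name in GROUPWISE_MEASURES else "pairwise"

    @property
    def label(self) -> str:
        return self.name if self.strategy is None else f"{self.strategy}-{self.name}"

    @classmethod
    def parse(cls, text: str) -> "MeasureSpec":
        """Parse specs like ``"gic"``, ``"resnik:bma"`` or ``"lin:average"``."""
        parts = text.strip().lower().split(":")
        name = _NAME_ALIASES.get(parts[0])
        if name is None:
            raise ValueError(f"unknown measure: {parts[0]!r}")
        if len(parts) == 1:
            strategy = "BMA" if name in PAIRWISE_MEASURES else None
        elif len(parts) == 2:
            strategy = _STRATEGY_ALIASES.get(parts[1])
            if strategy is None:
                raise ValueError(f"unknown strategy: {parts[1]!r}")
        else:
            raise ValueError(f"cannot parse measure spec: {text!r}")
        return cls(name, strategy)


# ------------------------------------------------------------- scalar layer


def mica(
    ic: ICTable, a: str, b: str, g: OntologyGraph
) -> tuple[str | None, float]:
    """Most informative common ancestor of two classes and its IC.

    Classes from different components share no ancestor; the result is then
    ``(None, 0.0)``.  Ties on IC break towards the lexicographically smallest
    class id for determinism.
    """
    common = g.ancestors(a) & g.ancestors(b)
    if not common:
        return None, 0.0
    best = min(common, key=lambda c: (-ic.ic[c], c))
    return best, ic.ic[best]


def pairwise_similarity(
    name: str, ic: ICTable, a: str, b: str, g: OntologyGraph
) -> float:
    """Class-class similarity under one of the pairwise measures.

    Resnik = IC(MICA); Lin = 2·IC(MICA)/(IC(a)+IC(b)) (0 when the denominator
    is 0); Jiang-Conrath = 1/(1 + IC(a) + IC(b) − 2·IC(MICA));
    Schlicker = Lin·(1 − p(MICA)), with p the topological occurrence proxy.
    """
    anc, mica_ic = mica(ic, a, b, g)
    if anc is None:
        # different components: no shared ancestor, no similarity
        return 0.0
    ic_a, ic_b = ic.ic[a], ic.ic[b]
    if name == "Resnik":
        return mica_ic
    if name == "Lin":
        denom = ic_a + ic_b
        return 2.0 * mica_ic / denom if denom > 0 else 0.0
    if name == "JiangConrath":
        return 1.0 / (1.0 + ic_a + ic_b - 2.0 * mica_ic)
    if name == "Schlicker":
        denom = ic_a + ic_b
        lin = 2.0 * mica_ic / denom if denom > 0 else 0.0
        p_mica = ic.p[anc] if anc is not None else 1.0
        return lin * (1.0 - p_mica)
    raise ValueError(f"unknown pairwise measure: {name}")


def combine_pairwise(strategy: str, scores: np.ndarray) -> float:
    """Mix a |A|x|B| class-pair score matrix into one entity-level score."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty pairwise score matrix")
    if strategy == "Average":
        return float(scores.mean())
    if strategy == "BMA":
        return float(0.5 * (scores.max(axis=1).mean() + scores.max(axis=0).mean()))
    if strategy == "Max":
        return float(scores.max())
    raise ValueError(f"unknown strategy: {strategy}")


def groupwise_similarity(
    name: str, ic: ICTable, a: AnnotationSet, b: AnnotationSet
) -> float:
    """Set similarity over the extended (ancestor-closed) annotation sets."""
    ea, eb = a.extended, b.extended
    if not ea or not eb:
        raise ValueError("groupwise similarity needs non-empty annotation sets")
    inter = ea & eb
    if name == "UI":
        return len(inter) / len(ea | eb)
    if name == "NTO":
        return len(inter) / min(len(ea), len(eb))
    if name == "GIC":
        union_ic = sum(ic.ic[c] for c in ea | eb)
        if union_ic == 0.0:
            return 1.0 if ea == eb else 0.0
        return sum(ic.ic[c] for c in inter) / union_ic
    raise ValueError(f"unknown groupwise measure: {name}")


def entity_similarity(
    measure: MeasureSpec,
    ic: ICTable,
    a: AnnotationSet,
    b: AnnotationSet,
    g: OntologyGraph,
) -> float:
    """Single entity-pair similarity via the scalar reference path."""
    if measure.kind == "groupwise":
        return groupwise_similarity(measure.name, ic, a, b)
    grid = np.array(
        [
            [pairwise_similarity(measure.name, ic, ca, cb, g) for cb in sorted(b.direct)]
            for ca in sorted(a.direct)
        ]
    )
    return combine_pairwise(measure.strategy, grid)


# --------------------------------------------------------- vectorized layer


def _term_tables(
    g: OntologyGraph, ic: ICTable, terms: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """MICA IC and MICA-p matrices over a fixed list of distinct classes.

    Classes are processed in increasing IC order and each writes its IC/p
    into the block of term pairs it subsumes; the final value of a cell is
    therefore the maximum IC over common ancestors.  Equal-IC classes within
    a component have equal p, so the p matrix is consistent regardless of
    tie order.
    """
    n = len(terms)
    mica_ic = np.zeros((n, n))
    mica_p = np.ones((n, n))
    members: dict[str, list[int]] = {}
    for i, t in enumerate(terms):
        for a in g.ancestors(t):
            members.setdefault(a, []).append(i)
    for c in sorted(members, key=lambda c: (ic.ic[c], c)):
        idx = np.fromiter(members[c], dtype=np.intp)
        mica_ic[np.ix_(idx, idx)] = ic.ic[c]
        mica_p[np.ix_(idx, idx)] = ic.p[c]
    return mica_ic, mica_p


def _pairwise_term_scores(
    name: str, g: OntologyGraph, ic: ICTable, terms: Sequence[str]
) -> np.ndarray:
    mica_ic, mica_p = _term_tables(g, ic, terms)
    t = np.array([ic.ic[c] for c in terms])
    comp = g.components()
    cvec = np.array([comp[c] for c in terms])
    same = cvec[:, None] == cvec[None, :]  # cross-component pairs score 0
    if name == "Resnik":
        return mica_ic
    denom = t[:, None] + t[None, :]
    if name == "JiangConrath":
        return np.where(same, 1.0 / (1.0 + denom - 2.0 * mica_ic), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = np.where(denom > 0, 2.0 * mica_ic / np.where(denom > 0, denom, 1.0), 0.0)
    if name == "Lin":
        return lin
    if name == "Schlicker":
        return lin * (1.0 - mica_p)
    raise ValueError(f"unknown pairwise measure: {name}")


@dataclass
class SimilarityMatrix:
    """Symmetric entity-by-entity similarity values for one measure."""

    entity_ids: list[str]
    values: np.ndarray
    measure: MeasureSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match entity count")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def __len__(self) -> int:
        return len(self.entity_ids)


def similarity_matrix(
    corpus: AnnotationCorpus,
    measure: MeasureSpec,
    g: OntologyGraph,
    ic: ICTable,
) -> SimilarityMatrix:
    """Full symmetric similarity matrix for a corpus under one measure.

    Raises :class:`ValueError` naming the entity if any entity is left with
    no usable (non-obsolete) annotation.
    """
    entities = corpus.entity_ids
    ann = [corpus.annotation_set(e, g) for e in entities]
    if measure.kind == "groupwise":
        values = _groupwise_matrix(measure.name, ic, ann)
    else:
        values = _pairwise_matrix(measure, g, ic, ann)
    return SimilarityMatrix(entities, values, measure)


def _groupwise_matrix(
    name: str, ic: ICTable, ann: list[AnnotationSet]
) -> np.ndarray:
    classes = sorted(set().union(*(a.extended for a in ann)))
    cidx = {c: i for i, c in enumerate(classes)}
    m, k = len(ann), len(classes)
    x = np.zeros((m, k))
    for i, a in enumerate(ann):
        x[i, [cidx[c] for c in a.extended]] = 1.0
    inter = x @ x.T
    sizes = x.sum(axis=1)
    if name == "UI":
        union = sizes[:, None] + sizes[None, :] - inter
        return inter / union
    if name == "NTO":
        return inter / np.minimum(sizes[:, None], sizes[None, :])
    if name == "GIC":
        w = np.array([ic.ic[c] for c in classes])
        inter_ic = (x * w) @ x.T
        s = x @ w
        union_ic = s[:, None] + s[None, :] - inter_ic
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(union_ic > 0, inter_ic / np.where(union_ic > 0, union_ic, 1.0),
                            (inter == union).astype(float))
    raise ValueError(f"unknown groupwise measure: {name}")


def _pairwise_matrix(
    measure: MeasureSpec,
    g: OntologyGraph,
    ic: ICTable,
    ann: list[AnnotationSet],
) -> np.ndarray:
    terms = sorted(set().union(*(a.direct for a in ann)))
    tidx = {c: i for i, c in enumerate(terms)}
    scores = _pairwise_term_scores(measure.name, g, ic, terms)
    idx_lists = [np.fromiter((tidx[c] for c in sorted(a.direct)), dtype=np.intp) for a in ann]
    m = len(ann)
    values = np.zeros((m, m))
    strategy = measure.strategy
    for i in range(m):
        rows = scores[idx_lists[i]]
        for j in range(i, m):
            sub = rows[:, idx_lists[j]]
            if strategy == "Average":
                v = sub.mean()
            elif strategy == "BMA":
                v = 0.5 * (sub.max(axis=1).mean() + sub.max(axis=0).mean())
            else:
                v = sub.max()
            values[i, j] = values[j, i] = v
    return values


# ----------------------------------------------------------------------- IO


def write_matrix_tsv(m: SimilarityMatrix, path: str | os.PathLike) -> None:
    """Wide TSV: entity ids as header row and first column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity\t" + "\t".join(m.entity_ids) + "\n")
        for i, e in enumerate(m.entity_ids):
            fh.write(e + "\t" + "\t".join(f"{v:.10g}" for v in m.values[i]) + "\n")


def write_matrix_long_tsv(
    m: SimilarityMatrix, path: str | os.PathLike, include_self: bool = False
) -> None:
    """Long TSV: one (entity_a, entity_b, score) row per unordered pair."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_a\tentity_b\tscore\n")
        n = len(m.entity_ids)
        for i in range(n):
            start = i if include_self else i + 1
            for j in range(start, n):
                fh.write(
                    f"{m.entity_ids[i]}\t{m.entity_ids[j]}\t{m.values[i, j]:.10g}\n"
                )
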