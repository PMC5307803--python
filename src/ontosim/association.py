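"""Interaction data, ROC evaluation and the randomized-annotation bias test.

Functional similarity is widely used to predict protein-protein
interactions: rank all gene pairs by similarity and treat known interactions
as positives.  Because curated interactomes are biased — well-studied genes
have both more annotations and more recorded interactions — a measure that
rewards large annotation sets can rank interacting pairs above chance even
after every annotation has been replaced by a random ontology class.
``bias_experiment`` quantifies exactly that: the ROC AUC obtained with real
annotations versus the AUC obtained with size-preserving randomized ones.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
from scipy import stats
from sklearn import metrics

from .bias import CorrelationResult, correlation_pair
from .corpus import AnnotationCorpus
from .measures import MeasureSpec, SimilarityMatrix, similarity_matrix
from .ontology import ICTable, OntologyGraph
from .synthetic import shuffle_annotations

__all__ = [
    "InteractionSet",
    "ROCResult",
    "read_gaf",
    "read_interaction_table",
    "roc_auc",
    "auc_permutation_pvalue",
    "bias_experiment",
    "annotation_degree_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionSet:
    """Unordered, distinct entity pairs (no self-interactions)."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-interaction not allowed: {a}")
            if a > b:
                raise ValueError("pairs must be stored in sorted order")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionSet":
        canon = {
            (a, b) if a < b else (b, a) for a, b in pairs if a != b
        }
        return cls(frozenset(canon))

    @property
    def entities(self) -> frozenset[str]:
        return frozenset(e for pair in self.pairs for e in pair)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a < b else (b, a)) in self.pairs

    def restricted_to(self, entities: Iterable[str]) -> "InteractionSet":
        keep = set(entities)
        return InteractionSet(
            frozenset(p for p in self.pairs if p[0] in keep and p[1] in keep)
        )

    def degrees(self, universe: Iterable[str]) -> dict[str, int]:
        """Interaction count per entity; absent entities count 0."""
        deg = {e: 0 for e in universe}
        for a, b in self.pairs:
            if a in deg:
                deg[a] += 1
            if b in deg:
                deg[b] += 1
        return deg


# ------------------------------------------------------------------ parsing

_GAF_COLUMNS = {"id": 1, "symbol": 2}


def _open_text(source: str | os.PathLike | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = os.fspath(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def read_gaf(
    source: str | os.PathLike | IO[str],
    excluded_evidence: Iterable[str] = frozenset({"ND"}),
    id_field: str = "symbol",
) -> AnnotationCorpus:
    """Read a GAF 2.x gene association file into an annotation corpus.

    Rows with an excluded evidence code (default: ND, "no data") or a NOT
    qualifier are dropped, duplicate (entity, class) pairs collapse to one,
    and malformed rows are skipped with a logged warning.
    """
    excluded = frozenset(excluded_evidence)
    col = _GAF_COLUMNS[id_field]
    annotations: dict[str, set[str]] = {}
    n_rows = n_kept = 0
    for lineno, raw in enumerate(_open_text(source), start=1):
        if raw.startswith("!") or not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 7:
            logger.warning("skipping malformed GAF row at line %d", lineno)
            continue
        n_rows += 1
        qualifier, go_id, evidence = fields[3], fields[4], fields[6]
        if evidence in excluded:
            continue
        if "NOT" in qualifier.split("|"):
            continue
        entity = fields[col]
        if not entity or not go_id:
            logger.warning("skipping GAF row with empty fields at line %d", lineno)
            continue
        annotations.setdefault(entity, set()).add(go_id)
        n_kept += 1
    if not annotations:
        raise ValueError("no annotations retained from GAF input")
    src = source if isinstance(source, (str, os.PathLike)) else "<stream>"
    return AnnotationCorpus(
        annotations,
        provenance={
            "source": os.fspath(src) if not isinstance(src, str) else src,
            "rows": n_rows,
            "kept": n_kept,
            "excluded_evidence": sorted(excluded),
        },
    )


def read_interaction_table(
    source: str | os.PathLike | IO[str],
    col_a: int = 0,
    col_b: int = 1,
    restrict_to: Iterable[str] | None = None,
) -> InteractionSet:
    """Read a two-column interaction TSV (BioGRID / SGD style).

    Pairs are deduplicated regardless of order and self-pairs dropped;
    ``restrict_to`` keeps only pairs whose both entities are in the given
    universe (e.g. the annotated genes).
    """
    need = max(col_a, col_b) + 1
    pairs: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(_open_text(source), start=1):
        if raw.startswith(("#", "!")) or not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < need:
            logger.warning("skipping short interaction row at line %d", lineno)
            continue
        a, b = fields[col_a].strip(), fields[col_b].strip()
        if not a or not b or a == b:
            continue
        pairs.add((a, b) if a < b else (b, a))
    result = InteractionSet(frozenset(pairs))
    if restrict_to is not None:
        result = result.restricted_to(restrict_to)
    return result


# -------------------------------------------------------------------- ROC


@dataclass
class ROCResult:
    """ROC curve points and area under the curve.

    ``auc`` is the rank-sum (Mann-Whitney) statistic with half credit for
    ties: the probability that a random positive pair outranks a random
    negative pair.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fpr\ttpr\n")
            for f, t in zip(self.fpr, self.tpr):
                fh.write(f"{f:.10g}\t{t:.10g}\n")


def _pair_scores_labels(
    m: SimilarityMatrix, positives: InteractionSet
) -> tuple[np.ndarray, np.ndarray]:
    known = set(m.entity_ids)
    missing = positives.entities - known
    restricted = positives.restricted_to(known) if missing else positives
    if len(restricted) == 0:
        raise ValueError("no positive pairs remain within the similarity matrix")
    idx = {e: i for i, e in enumerate(m.entity_ids)}
    iu, ju = np.triu_indices(len(m.entity_ids), k=1)
    scores = m.values[iu, ju]
    labels = np.zeros(scores.shape, dtype=bool)
    rows = np.fromiter((idx[a] for a, b in restricted.pairs), dtype=np.intp)
    cols = np.fromiter((idx[b] for a, b in restricted.pairs), dtype=np.intp)
    lo, hi = np.minimum(rows, cols), np.maximum(rows, cols)
    n = len(m.entity_ids)
    # map (lo, hi) with lo < hi to its position in the upper-triangle order
    flat = (lo * (2 * n - lo - 1)) // 2 + (hi - lo - 1)
    labels[flat] = True
    return scores, labels


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative pair")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(
    m: SimilarityMatrix, positives: InteractionSet, max_curve_points: int = 2000
) -> ROCResult:
    """ROC of similarity scores against known interactions.

    All unordered non-self entity pairs are ranked by similarity; pairs in
    ``positives`` (restricted to the matrix universe) are the positive class
    and every other pair is a negative.  The curve is thinned to at most
    ``max_curve_points`` points for output; the AUC is exact.
    """
    scores, labels = _pair_scores_labels(m, positives)
    auc = _rank_auc(scores, labels)
    fpr, tpr, _ = metrics.roc_curve(labels, scores)
    if fpr.size > max_curve_points:
        keep = np.unique(
            np.concatenate(
                [[0, fpr.size - 1], np.linspace(0, fpr.size - 1, max_curve_points).astype(int)]
            )
        )
        fpr, tpr = fpr[keep], tpr[keep]
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc)


def auc_permutation_pvalue(
    m: SimilarityMatrix,
    positives: InteractionSet,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """One-sided permutation p-value for AUC > 0.5.

    The positive label set is re-drawn uniformly among all pairs
    ``n_permutations`` times (the scores stay fixed); the p-value is the
    add-one-smoothed fraction of permuted AUCs at least as large as the
    observed one.  Returns ``(observed_auc, p_value)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores, labels = _pair_scores_labels(m, positives)
    observed = _rank_auc(scores, labels)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    offset = n_pos * (n_pos + 1) / 2
    hits = 0
    for _ in range(n_permutations):
        perm = rng.choice(labels.size, size=n_pos, replace=False)
        auc = (ranks[perm].sum() - offset) / (n_pos * n_neg)
        if auc >= observed:
            hits += 1
    return observed, (hits + 1) / (n_permutations + 1)


def bias_experiment(
    corpus: AnnotationCorpus,
    g: OntologyGraph,
    ic: ICTable,
    positives: InteractionSet,
    measure: MeasureSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[ROCResult, ROCResult]:
    """ROC with real annotations versus size-preserving random annotations.

    The same entity universe and the same positive pairs are scored twice:
    once from the corpus as given and once after ``shuffle_annotations``
    replaced every class by a random one (annotation counts preserved).  A
    gap between the two AUCs that fails to close under randomization is the
    annotation-size bias at work.
    """
    real_matrix = similarity_matrix(corpus, measure, g, ic)
    real = roc_auc(real_matrix, positives)
    shuffled = shuffle_annotations(corpus, g, seed)
    random_matrix = similarity_matrix(shuffled, measure, g, ic)
    randomized = roc_auc(random_matrix, positives)
    return real, randomized


def annotation_degree_correlation(
    corpus: AnnotationCorpus, positives: InteractionSet
) -> CorrelationResult:
    """Correlation between annotation counts and interaction degrees.

    Computed over the corpus entities; entities absent from the network have
    degree 0.  This is the confounder that lets size-sensitive measures
    predict interactions from meaningless annotations.
    """
    entities = corpus.entity_ids
    sizes = [len(corpus[e]) for e in entities]
    deg = positives.degrees(entities)
    degrees = [deg[e] for e in entities]
    return correlation_pair(sizes, degrees)
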