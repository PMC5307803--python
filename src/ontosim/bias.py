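"""Sensitivity profiles: how similarity depends on annotation size and depth.

The audit works on a full similarity matrix over a grouped corpus:

* the *group profile* averages, for each entity, its similarity to every
  other entity, then summarizes those per-entity means within each group
  (annotation size or class depth);
* the *difference profile* bins all unordered entity pairs by the absolute
  difference of their annotation sizes and summarizes the raw pair scores
  per bin;
* Spearman and Pearson coefficients over the group keys versus the group
  means (and versus the group variances) quantify the sensitivity, and the
  Pearson coefficient on the size profile classifies a measure as
  positively correlated (r > 0.5), uncorrelated, or negatively correlated
  (r < -0.5) with annotation size.

Self-similarities are excluded from every average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import AnnotationCorpus
from .measures import SimilarityMatrix

__all__ = [
    "GroupProfile",
    "CorrelationResult",
    "group_profile",
    "difference_profile",
    "correlation_pair",
    "classify_measure",
    "profile_correlations",
]


@dataclass
class GroupProfile:
    """Per-group mean/variance/count summary of similarity values.

    ``table`` has columns ``group`` (sorted ascending), ``mean``,
    ``variance`` (population variance, 0 for singleton groups) and ``n``.
    """

    grouping: str
    table: pd.DataFrame

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    @property
    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy()

    @property
    def variances(self) -> np.ndarray:
        return self.table["variance"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass(frozen=True)
class CorrelationResult:
    spearman: float
    pearson: float
    n: int


def _group_labels(m: SimilarityMatrix, corpus: AnnotationCorpus, grouping: str) -> np.ndarray:
    if set(m.entity_ids) != set(corpus.entity_ids):
        raise ValueError("similarity matrix and corpus cover different entities")
    if grouping == "size":
        if corpus.grouping == "size" and corpus.group_labels is not None:
            labels = corpus.group_labels
        else:
            labels = corpus.sizes()
    elif grouping == "depth":
        if corpus.grouping != "depth" or corpus.group_labels is None:
            raise ValueError("corpus carries no depth group labels")
        labels = corpus.group_labels
    else:
        raise ValueError(f"unknown grouping: {grouping}")
    return np.array([labels[e] for e in m.entity_ids])


def group_profile(
    m: SimilarityMatrix, corpus: AnnotationCorpus, grouping: str = "size"
) -> GroupProfile:
    """Average similarity of each group's entities to the rest of the corpus.

    Each entity's score is its mean similarity to all *other* entities; the
    profile reports the mean and population variance of those per-entity
    scores within each group.
    """
    labels = _group_labels(m, corpus, grouping)
    n = len(m.entity_ids)
    if n < 2:
        raise ValueError("profile needs at least two entities")
    v = m.values
    per_entity = (v.sum(axis=1) - np.diag(v)) / (n - 1)
    frame = pd.DataFrame({"group": labels, "value": per_entity})
    table = (
        frame.groupby("group")["value"]
        .agg(mean="mean", variance=lambda x: float(np.var(x)), n="size")
        .reset_index()
        .sort_values("group", ignore_index=True)
    )
    return GroupProfile(grouping, table)


def difference_profile(m: SimilarityMatrix, corpus: AnnotationCorpus) -> GroupProfile:
    """Raw pair similarities binned by absolute annotation-size difference.

    Every unordered pair (i < j) contributes once; self-pairs are excluded.
    """
    labels = _group_labels(m, corpus, "size")
    iu, ju = np.triu_indices(len(m.entity_ids), k=1)
    delta = np.abs(labels[iu] - labels[ju])
    vals = m.values[iu, ju]
    frame = pd.DataFrame({"group": delta, "value": vals})
    table = (
        frame.groupby("group")["value"]
        .agg(mean="mean", variance=lambda x: float(np.var(x)), n="size")
        .reset_index()
        .sort_values("group", ignore_index=True)
    )
    return GroupProfile("size_difference", table)


def correlation_pair(xs, ys) -> CorrelationResult:
    """Spearman and Pearson coefficients between matched vectors.

    Requires at least three points and non-constant inputs (the coefficients
    are undefined otherwise).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be matched one-dimensional vectors")
    if xs.size < 3:
        raise ValueError("correlation needs at least three points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation is undefined for constant input")
    pearson = stats.pearsonr(xs, ys).statistic
    spearman = stats.spearmanr(xs, ys).statistic
    return CorrelationResult(spearman=float(spearman), pearson=float(pearson), n=int(xs.size))


def classify_measure(pearson_r: float) -> str:
    """Classify size sensitivity from the Pearson r of the size profile.

    Strictly above 0.5 is ``positive``, strictly below -0.5 is ``negative``,
    anything in between (boundaries included) is ``none``.
    """
    if not -1.0 <= pearson_r <= 1.0:
        raise ValueError("Pearson r must lie in [-1, 1]")
    if pearson_r > 0.5:
        return "positive"
    if pearson_r < -0.5:
        return "negative"
    return "none"


def profile_correlations(profile: GroupProfile) -> dict[str, CorrelationResult]:
    """Key-vs-mean and key-vs-variance correlations of a profile.

    Mirrors the two summary columns reported per measure: how the average
    similarity and the variance of similarity move with the group key.
    Constant variance vectors yield a ``None`` entry instead of an error.
    """
    out: dict[str, CorrelationResult | None] = {}
    out["average"] = correlation_pair(profile.groups, profile.means)
    try:
        out["variance"] = correlation_pair(profile.groups, profile.variances)
    except ValueError:
        out["variance"] = None
    return out
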