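"""Annotation corpora: entity-to-class mappings with optional group labels.

A corpus maps each entity (gene, protein, disease, synthetic id) to its set
of *direct* ontology classes.  The *extended* set — the union of ancestor
closures of the direct classes — is what groupwise measures operate on.
Group labels carry the experimental design: the entity's annotation size,
or the depth of its annotation classes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .ontology import OntologyGraph

__all__ = ["AnnotationSet", "AnnotationCorpus", "read_corpus_tsv", "write_corpus_tsv"]


@dataclass(frozen=True)
class AnnotationSet:
    """One entity's direct annotations plus their ancestor closure."""

    entity_id: str
    direct: frozenset[str]
    extended: frozenset[str]

    @property
    def size(self) -> int:
        """Annotation size |A|: the number of direct classes."""
        return len(self.direct)


class AnnotationCorpus:
    """Ordered mapping entity id -> direct class set, with group labels.

    ``grouping`` records what the labels mean: ``"size"`` (annotation count),
    ``"depth"`` (class depth shared by the entity's annotations) or ``None``.
    """

    def __init__(
        self,
        annotations: Mapping[str, Iterable[str]],
        grouping: str | None = None,
        group_labels: Mapping[str, int] | None = None,
        provenance: dict | None = None,
    ) -> None:
        self.annotations: dict[str, frozenset[str]] = {
            e: frozenset(classes) for e, classes in annotations.items()
        }
        for e, classes in self.annotations.items():
            if not classes:
                raise ValueError(f"entity {e} has an empty annotation set")
        if grouping not in (None, "size", "depth"):
            raise ValueError(f"unknown grouping: {grouping}")
        self.grouping = grouping
        self.group_labels: dict[str, int] | None = (
            dict(group_labels) if group_labels is not None else None
        )
        if self.group_labels is not None and set(self.group_labels) != set(self.annotations):
            raise ValueError("group labels must cover exactly the corpus entities")
        self.provenance: dict = dict(provenance or {})

    # -------------------------------------------------------------- protocol

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[str]:
        return iter(self.annotations)

    def __contains__(self, entity: str) -> bool:
        return entity in self.annotations

    def __getitem__(self, entity: str) -> frozenset[str]:
        return self.annotations[entity]

    @property
    def entity_ids(self) -> list[str]:
        return list(self.annotations)

    def sizes(self) -> dict[str, int]:
        return {e: len(a) for e, a in self.annotations.items()}

    def labels(self) -> dict[str, int]:
        """Group labels; for a size grouping they default to annotation sizes."""
        if self.group_labels is not None:
            return dict(self.group_labels)
        if self.grouping in (None, "size"):
            return self.sizes()
        raise ValueError(f"corpus has grouping {self.grouping!r} but no labels")

    # ------------------------------------------------------------- structure

    def annotation_set(self, entity: str, g: OntologyGraph) -> AnnotationSet:
        direct = self.annotations[entity]
        active = frozenset(c for c in direct if g.is_active(c))
        if not active:
            raise ValueError(
                f"entity {entity} has no non-obsolete annotations"
            )
        extended: set[str] = set()
        for c in active:
            extended |= g.ancestors(c)
        return AnnotationSet(entity, active, frozenset(extended))

    def restricted_to(self, entities: Iterable[str]) -> "AnnotationCorpus":
        keep = [e for e in self.annotations if e in set(entities)]
        labels = (
            {e: self.group_labels[e] for e in keep} if self.group_labels is not None else None
        )
        return AnnotationCorpus(
            {e: self.annotations[e] for e in keep},
            grouping=self.grouping,
            group_labels=labels,
            provenance={**self.provenance, "restricted": True},
        )


# ----------------------------------------------------------------------- IO


def write_corpus_tsv(
    corpus: AnnotationCorpus,
    path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
) -> None:
    """Write a corpus as two-column TSV (entity, class), one annotation per row."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in corpus.entity_ids:
            for c in sorted(corpus[e]):
                fh.write(f"{e}\t{c}\n")
    if labels_path is not None and corpus.group_labels is not None:
        with open(labels_path, "w", encoding="utf-8") as fh:
            fh.write(f"entity\t{corpus.grouping or 'group'}\n")
            for e in corpus.entity_ids:
                fh.write(f"{e}\t{corpus.group_labels[e]}\n")


def read_corpus_tsv(
    path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
    grouping: str | None = None,
) -> AnnotationCorpus:
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            entity, cls = line.split("\t")[:2]
            annotations.setdefault(entity, set()).add(cls)
    labels: dict[str, int] | None = None
    if labels_path is not None:
        labels = {}
        with open(labels_path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if grouping is None and len(header) > 1 and header[1] in ("size", "depth"):
                grouping = header[1]
            for raw in fh:
                if not raw.strip():
                    continue
                entity, label = raw.rstrip("\n").split("\t")[:2]
                labels[entity] = int(label)
    return AnnotationCorpus(
        annotations,
        grouping=grouping,
        group_labels=labels,
        provenance={"source": os.fspath(path)},
    )
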