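"""Orchestration of the bias-audit stages into reproducible runs.

A :class:`RunConfig` fixes everything a run depends on — ontology source,
corpus source (file or synthetic spec), measures, seed — and every run
writes a ``manifest.json`` echoing the resolved configuration, input file
hashes and outputs, so identical configurations yield byte-identical
numeric results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .association import (
    InteractionSet,
    annotation_degree_correlation,
    auc_permutation_pvalue,
    bias_experiment,
    read_gaf,
    read_interaction_table,
)
from .bias import (
    classify_measure,
    difference_profile,
    group_profile,
    profile_correlations,
)
from .corpus import AnnotationCorpus, read_corpus_tsv, write_corpus_tsv
from .measures import (
    MeasureSpec,
    similarity_matrix,
    write_matrix_long_tsv,
    write_matrix_tsv,
)
from .ontology import OntologyGraph, compute_intrinsic_ic, parse_obo
from .synthetic import (
    annotate_by_depth,
    annotate_by_size,
    generate_layered_dag,
    generate_random_dag,
)

__all__ = ["RunConfig", "run_bias_suite", "run_ppi_eval"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for a bias-suite or PPI-evaluation run."""

    out_dir: str
    seed: int = 0
    obo_path: str | None = None
    relations: tuple[str, ...] = ("is_a", "part_of")
    corpus_path: str | None = None
    labels_path: str | None = None
    synthetic_classes: int | None = None
    dag_kind: str = "layered"
    synthetic_max_parents: int = 3
    measures: tuple[str, ...] = ("gic", "resnik:bma")
    sizes: tuple[int, ...] = tuple(range(1, 21))
    per_group: int = 20
    depths: tuple[int, ...] | None = None
    size_per_entity: int = 10
    analyses: tuple[str, ...] = ("size", "difference")
    gaf_path: str | None = None
    interactions_path: str | None = None
    interaction_cols: tuple[int, int] = (0, 1)
    excluded_evidence: tuple[str, ...] = ("ND",)
    n_permutations: int = 200

    def resolved_measures(self) -> list[MeasureSpec]:
        return [MeasureSpec.parse(m) for m in self.measures]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, out: Path, status: str, outputs: list[str]) -> None:
    inputs = {}
    for name in ("obo_path", "corpus_path", "labels_path", "gaf_path", "interactions_path"):
        path = getattr(config, name)
        if path is not None and os.path.exists(path):
            inputs[name] = {"path": path, "sha256": _sha256(path)}
    manifest = {
        "tool": "ontosim",
        "version": __version__,
        "status": status,
        "config": asdict(config),
        "inputs": inputs,
        "outputs": sorted(outputs),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_ontology(config: RunConfig, rng: np.random.Generator) -> OntologyGraph:
    if config.obo_path is not None:
        logger.info("parsing ontology from %s", config.obo_path)
        return parse_obo(config.obo_path, config.relations)
    if config.synthetic_classes is None:
        raise ValueError("config needs either obo_path or synthetic_classes")
    logger.info("generating %s random DAG with %d classes", config.dag_kind,
                config.synthetic_classes)
    if config.dag_kind == "layered":
        return generate_layered_dag(config.synthetic_classes, seed=rng)
    if config.dag_kind == "uniform":
        return generate_random_dag(
            config.synthetic_classes, config.synthetic_max_parents, rng
        )
    raise ValueError(f"unknown dag_kind: {config.dag_kind}")


def _load_corpus(
    config: RunConfig, g: OntologyGraph, rng: np.random.Generator, grouping: str
) -> AnnotationCorpus:
    if config.corpus_path is not None:
        return read_corpus_tsv(config.corpus_path, config.labels_path)
    if grouping == "depth":
        depths = config.depths
        if depths is None:
            present = sorted(set(g.depths().values()) - {0})
            depths = tuple(present)
        return annotate_by_depth(
            g, depths, config.per_group, config.size_per_entity, rng
        )
    return annotate_by_size(g, config.sizes, config.per_group, rng)


def run_bias_suite(config: RunConfig) -> dict:
    """Run the size / size-difference / depth sensitivity analyses.

    For each configured measure, writes the requested profiles, a combined
    correlation table mirroring the published layout, and the size-based
    classification label.  Returns a summary dict (also written as TSV).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    try:
        seeds = np.random.SeedSequence(config.seed).spawn(3)
        g = _load_ontology(config, np.random.default_rng(seeds[0]))
        ic = compute_intrinsic_ic(g)
        corpora: dict[str, AnnotationCorpus] = {}
        if {"size", "difference"} & set(config.analyses):
            corpora["size"] = _load_corpus(config, g, np.random.default_rng(seeds[1]), "size")
        if "depth" in config.analyses:
            corpora["depth"] = _load_corpus(config, g, np.random.default_rng(seeds[2]), "depth")
        for key, corpus in corpora.items():
            path = out / f"corpus_{key}.tsv"
            write_corpus_tsv(corpus, path, out / f"corpus_{key}.labels.tsv")
            outputs += [str(path), str(out / f"corpus_{key}.labels.tsv")]
        rows = []
        for spec in config.resolved_measures():
            t0 = time.perf_counter()
            row: dict = {"measure": spec.label}
            if "size" in corpora:
                m = similarity_matrix(corpora["size"], spec, g, ic)
                logger.info(
                    "%s: %dx%d matrix in %.1fs", spec.label, len(m), len(m),
                    time.perf_counter() - t0,
                )
                if "size" in config.analyses:
                    prof = group_profile(m, corpora["size"], "size")
                    prof.to_tsv(out / f"profile_size_{spec.label}.tsv")
                    outputs.append(str(out / f"profile_size_{spec.label}.tsv"))
                    corr = profile_correlations(prof)
                    row.update(_corr_cols("size", corr))
                    row["classification"] = classify_measure(corr["average"].pearson)
                if "difference" in config.analyses:
                    prof = difference_profile(m, corpora["size"])
                    prof.to_tsv(out / f"profile_diff_{spec.label}.tsv")
                    outputs.append(str(out / f"profile_diff_{spec.label}.tsv"))
                    row.update(_corr_cols("diff", profile_correlations(prof)))
            if "depth" in corpora:
                m = similarity_matrix(corpora["depth"], spec, g, ic)
                prof = group_profile(m, corpora["depth"], "depth")
                prof.to_tsv(out / f"profile_depth_{spec.label}.tsv")
                outputs.append(str(out / f"profile_depth_{spec.label}.tsv"))
                row.update(_corr_cols("depth", profile_correlations(prof)))
            rows.append(row)
        import pandas as pd

        table = pd.DataFrame(rows)
        table.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.6f")
        outputs.append(str(out / "correlations.tsv"))
        _write_manifest(config, out, "ok", outputs)
        return {"table": table, "out_dir": str(out)}
    except Exception:
        _write_manifest(config, out, "failed", outputs)
        raise


def _corr_cols(prefix: str, corr: dict) -> dict:
    cols = {}
    avg = corr["average"]
    cols[f"{prefix}_avg_spearman"] = avg.spearman
    cols[f"{prefix}_avg_pearson"] = avg.pearson
    var = corr["variance"]
    cols[f"{prefix}_var_spearman"] = var.spearman if var else float("nan")
    cols[f"{prefix}_var_pearson"] = var.pearson if var else float("nan")
    return cols


def run_ppi_eval(config: RunConfig) -> dict:
    """Real-vs-randomized interaction prediction for each configured measure.

    Writes ROC curves and an AUC summary with the annotation/degree
    correlation and a label-permutation p-value per measure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    try:
        seeds = np.random.SeedSequence(config.seed).spawn(2)
        g = _load_ontology(config, np.random.default_rng(seeds[0]))
        ic = compute_intrinsic_ic(g)
        if config.gaf_path is not None:
            corpus = read_gaf(config.gaf_path, set(config.excluded_evidence))
        elif config.corpus_path is not None:
            corpus = read_corpus_tsv(config.corpus_path, config.labels_path)
        else:
            raise ValueError("ppi evaluation needs gaf_path or corpus_path")
        if config.interactions_path is None:
            raise ValueError("ppi evaluation needs interactions_path")
        positives = read_interaction_table(
            config.interactions_path,
            *config.interaction_cols,
            restrict_to=corpus.entity_ids,
        )
        if len(positives) == 0:
            raise ValueError("no interactions overlap the annotated entities")
        degree_corr = annotation_degree_correlation(corpus, positives)
        rows = []
        from .association import roc_auc
        from .synthetic import shuffle_annotations

        shuffled = shuffle_annotations(corpus, g, np.random.default_rng(seeds[1]))
        for spec in config.resolved_measures():
            m_real = similarity_matrix(corpus, spec, g, ic)
            real = roc_auc(m_real, positives)
            m_rand = similarity_matrix(shuffled, spec, g, ic)
            randomized = roc_auc(m_rand, positives)
            real.to_tsv(out / f"roc_real_{spec.label}.tsv")
            randomized.to_tsv(out / f"roc_random_{spec.label}.tsv")
            outputs += [
                str(out / f"roc_real_{spec.label}.tsv"),
                str(out / f"roc_random_{spec.label}.tsv"),
            ]
            _, pvalue = auc_permutation_pvalue(
                m_real, positives, config.n_permutations, np.random.default_rng(seeds[1])
            )
            rows.append(
                {
                    "measure": spec.label,
                    "auc_real": real.auc,
                    "auc_random": randomized.auc,
                    "p_permutation": pvalue,
                    "annotation_degree_pearson": degree_corr.pearson,
                    "n_positives": len(positives),
                }
            )
        import pandas as pd

        table = pd.DataFrame(rows)
        table.to_csv(out / "auc_summary.tsv", sep="\t", index=False, float_format="%.6f")
        outputs.append(str(out / "auc_summary.tsv"))
        _write_manifest(config, out, "ok", outputs)
        return {"table": table, "out_dir": str(out)}
    except Exception:
        _write_manifest(config, out, "failed", outputs)
        raise
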