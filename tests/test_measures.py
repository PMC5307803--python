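"""Pairwise and groupwise similarity measures, mixing strategies, matrices."""

import numpy as np
import pytest

from ontosim import (
    AnnotationCorpus,
    MeasureSpec,
    combine_pairwise,
    compute_intrinsic_ic,
    entity_similarity,
    groupwise_similarity,
    mica,
    pairwise_similarity,
    similarity_matrix,
)
from ontosim.measures import write_matrix_long_tsv, write_matrix_tsv
from ontosim.synthetic import annotate_by_size, generate_random_dag

from conftest import random_dag


class TestMeasureSpec:
    @pytest.mark.parametrize(
        "text, name, strategy",
        [
            ("gic", "GIC", None),
            ("simgic", "GIC", None),
            ("resnik:bma", "Resnik", "BMA"),
            ("jc:average", "JiangConrath", "Average"),
            ("LIN:MAX", "Lin", "Max"),
            ("resnik", "Resnik", "BMA"),  # pairwise defaults to BMA
        ],
    )
    def test_parse(self, text, name, strategy):
        spec = MeasureSpec.parse(text)
        assert (spec.name, spec.strategy) == (name, strategy)

    def test_strategy_present_iff_pairwise(self):
        with pytest.raises(ValueError):
            MeasureSpec("GIC", "BMA")
        with pytest.raises(ValueError):
            MeasureSpec("Resnik", None)
        with pytest.raises(ValueError):
            MeasureSpec.parse("nosuch")


class TestMica:
    def test_t1_mica(self, t1, t1_ic):
        assert mica(t1_ic, "C", "D", t1) == ("A", pytest.approx(0.317394, abs=1e-6))
        assert mica(t1_ic, "C", "C", t1) == ("C", 1.0)

    def test_disjoint_components_have_no_mica(self):
        import io

        from ontosim import parse_obo

        g = parse_obo(io.StringIO(
            "format-version: 1.2\n\n[Term]\nid: A\n\n[Term]\nid: B\n"
        ))
        ic = compute_intrinsic_ic(g)
        assert mica(ic, "A", "B", g) == (None, 0.0)


class TestPairwiseSimilarity:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("Resnik", 0.317394),
            ("Lin", 0.317394),
            ("JiangConrath", 0.422795),
            ("Schlicker", 0.126958),
        ],
    )
    def test_t1_c_vs_d(self, t1, t1_ic, name, expected):
        assert pairwise_similarity(name, t1_ic, "C", "D", t1) == pytest.approx(
            expected, abs=1e-6
        )

    def test_identity_of_leaves(self, t1, t1_ic):
        assert pairwise_similarity("Lin", t1_ic, "C", "C", t1) == 1.0
        assert pairwise_similarity("JiangConrath", t1_ic, "C", "C", t1) == 1.0

    def test_unknown_measure_raises(self, t1, t1_ic):
        with pytest.raises(ValueError):
            pairwise_similarity("Cosine", t1_ic, "C", "D", t1)


class TestCombinePairwise:
    def test_bma_and_average_on_hand_matrix(self):
        grid = np.array([[1.0, 0.0]])  # {C} vs {C, B} under Resnik on T1
        assert combine_pairwise("BMA", grid) == pytest.approx(0.75)
        assert combine_pairwise("Average", grid) == pytest.approx(0.5)
        assert combine_pairwise("Max", grid) == 1.0

    def test_identical_singletons(self):
        for strategy in ("Average", "BMA", "Max"):
            assert combine_pairwise(strategy, np.array([[1.0]])) == 1.0

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            combine_pairwise("BMA", np.zeros((0, 0)))


class TestGroupwiseSimilarity:
    @pytest.mark.parametrize(
        "name, expected",
        [("UI", 0.5), ("GIC", 0.136962), ("NTO", 2 / 3)],
    )
    def test_t1_c_vs_d_sets(self, t1, t1_ic, name, expected):
        corpus = AnnotationCorpus({"a": {"C"}, "b": {"D"}})
        a = corpus.annotation_set("a", t1)
        b = corpus.annotation_set("b", t1)
        assert groupwise_similarity(name, t1_ic, a, b) == pytest.approx(expected, abs=1e-6)

    def test_self_similarity_is_one(self, t1, t1_ic):
        corpus = AnnotationCorpus({"a": {"C", "B"}})
        a = corpus.annotation_set("a", t1)
        for name in ("GIC", "UI", "NTO"):
            assert groupwise_similarity(name, t1_ic, a, a) == 1.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_set_arithmetic(self, seed):
        g = random_dag(30, 2, seed)
        ic = compute_intrinsic_ic(g)
        corpus = annotate_by_size(g, [1, 2, 3], 3, seed=seed)
        ids = corpus.entity_ids
        for i in range(0, len(ids), 2):
            a = corpus.annotation_set(ids[i], g)
            b = corpus.annotation_set(ids[(i + 3) % len(ids)], g)
            ea, eb = set(a.extended), set(b.extended)
            assert groupwise_similarity("UI", ic, a, b) == pytest.approx(
                len(ea & eb) / len(ea | eb)
            )
            assert groupwise_similarity("NTO", ic, a, b) == pytest.approx(
                len(ea & eb) / min(len(ea), len(eb))
            )
            assert groupwise_similarity("GIC", ic, a, b) == pytest.approx(
                sum(ic.ic[c] for c in ea & eb) / sum(ic.ic[c] for c in ea | eb)
            )


class TestSimilarityMatrix:
    def test_identical_entities_give_unit_gic_matrix(self, t1, t1_ic):
        corpus = AnnotationCorpus({"a": {"C"}, "b": {"C"}})
        m = similarity_matrix(corpus, MeasureSpec.parse("gic"), t1, t1_ic)
        assert np.allclose(m.values, 1.0)

    @pytest.mark.parametrize(
        "text", ["gic", "ui", "nto", "resnik:bma", "lin:average", "jc:max", "schlicker:bma"]
    )
    def test_matrix_matches_elementwise_scalar_path(self, t1, t1_ic, t1_corpus, text):
        spec = MeasureSpec.parse(text)
        m = similarity_matrix(t1_corpus, spec, t1, t1_ic)
        ann = {e: t1_corpus.annotation_set(e, t1) for e in t1_corpus.entity_ids}
        for i, a in enumerate(t1_corpus.entity_ids):
            for j, b in enumerate(t1_corpus.entity_ids):
                assert m.values[i, j] == pytest.approx(
                    entity_similarity(spec, t1_ic, ann[a], ann[b], t1), abs=1e-12
                )

    def test_entity_with_only_obsolete_annotation_is_named(self, t1):
        import io

        from ontosim import parse_obo

        g = parse_obo(io.StringIO(
            "format-version: 1.2\n\n[Term]\nid: A\n\n[Term]\nid: OBS\nis_obsolete: true\n"
        ))
        ic = compute_intrinsic_ic(g)
        corpus = AnnotationCorpus({"good": {"A"}, "bad": {"OBS"}})
        with pytest.raises(ValueError, match="bad"):
            similarity_matrix(corpus, MeasureSpec.parse("gic"), g, ic)

    def test_empty_annotation_set_rejected_at_construction(self):
        with pytest.raises(ValueError, match="empty"):
            AnnotationCorpus({"e": set()})

    @pytest.mark.parametrize("seed", [11, 12])
    @pytest.mark.parametrize(
        "text", ["gic", "nto", "ui", "resnik:bma", "lin:bma", "jc:bma", "lin:max", "schlicker:bma"]
    )
    def test_symmetry_bounds_self_maximality_on_random_corpora(self, seed, text):
        g = random_dag(60, 3, seed)
        ic = compute_intrinsic_ic(g)
        corpus = annotate_by_size(g, [1, 2, 4], 4, seed=seed)
        spec = MeasureSpec.parse(text)
        m = similarity_matrix(corpus, spec, g, ic)
        assert np.allclose(m.values, m.values.T)
        upper = ic.max_ic if spec.name == "Resnik" else 1.0 + 1e-12
        assert (m.values >= -1e-12).all() and (m.values <= upper).all()
        diag = np.diag(m.values)
        if spec.kind == "groupwise":
            # a set is never more similar to another set than to itself
            assert (diag[:, None] + 1e-12 >= m.values).all()
        else:
            # BMA/Average/Max obey the weaker pairwise bound
            # sim(X, Y) <= (self(X) + self(Y)) / 2 only for BMA/Average;
            # Max is bounded by the larger self-similarity
            if spec.strategy in ("Average", "BMA"):
                bound = 0.5 * (diag[:, None] + diag[None, :])
            else:
                bound = np.maximum(diag[:, None], diag[None, :])
            assert (bound + 1e-12 >= m.values).all()

    def test_bma_lin_of_identical_sets_is_one(self, t1, t1_ic):
        corpus = AnnotationCorpus({"a": {"C", "B"}, "b": {"C", "B"}})
        m = similarity_matrix(corpus, MeasureSpec.parse("lin:bma"), t1, t1_ic)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_matrix_tsv_roundtrip_shapes(self, t1, t1_ic, t1_corpus, tmp_path):
        m = similarity_matrix(t1_corpus, MeasureSpec.parse("gic"), t1, t1_ic)
        wide, long = tmp_path / "m.tsv", tmp_path / "m.long.tsv"
        write_matrix_tsv(m, wide)
        write_matrix_long_tsv(m, long)
        import pandas as pd

        w = pd.read_csv(wide, sep="\t", index_col=0)
        assert list(w.columns) == m.entity_ids
        assert np.allclose(w.to_numpy(), m.values)
        l = pd.read_csv(long, sep="\t")
        assert len(l) == len(m) * (len(m) - 1) // 2
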