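"""GAF/interaction parsing, ROC computation and the bias experiment."""

import io
import itertools

import numpy as np
import pytest

from ontosim import (
    AnnotationCorpus,
    InteractionSet,
    MeasureSpec,
    SimilarityMatrix,
    annotation_degree_correlation,
    auc_permutation_pvalue,
    bias_experiment,
    compute_intrinsic_ic,
    read_gaf,
    read_interaction_table,
    roc_auc,
    similarity_matrix,
)
from ontosim.synthetic import annotate_by_size, generate_layered_dag

GAF = """\
!gaf-version: 2.1
SGD\tS000001\tGENE1\t\tGO:0000001\tPMID:1\tIDA\t\tP\t\t\tgene\ttaxon:4932\t20160101\tSGD
SGD\tS000001\tGENE1\t\tGO:0000002\tPMID:1\tND\t\tP\t\t\tgene\ttaxon:4932\t20160101\tSGD
SGD\tS000002\tGENE2\t\tGO:0000002\tPMID:2\tIEA\t\tP\t\t\tgene\ttaxon:4932\t20160101\tSGD
SGD\tS000002\tGENE2\t\tGO:0000002\tPMID:3\tIDA\t\tP\t\t\tgene\ttaxon:4932\t20160101\tSGD
SGD\tS000003\tGENE3\tNOT\tGO:0000003\tPMID:4\tIDA\t\tP\t\t\tgene\ttaxon:4932\t20160101\tSGD
"""


class TestReadGaf:
    def test_evidence_not_and_duplicates_handled(self):
        corpus = read_gaf(io.StringIO(GAF))
        # GENE1 loses its ND row, GENE2's duplicate collapses, GENE3's NOT row drops
        assert set(corpus.entity_ids) == {"GENE1", "GENE2"}
        assert corpus["GENE1"] == {"GO:0000001"}
        assert corpus["GENE2"] == {"GO:0000002"}

    def test_no_exclusion_keeps_nd(self):
        corpus = read_gaf(io.StringIO(GAF), excluded_evidence=())
        assert corpus["GENE1"] == {"GO:0000001", "GO:0000002"}

    def test_id_field_selects_object_id_column(self):
        corpus = read_gaf(io.StringIO(GAF), id_field="id")
        assert set(corpus.entity_ids) == {"S000001", "S000002"}

    def test_malformed_row_skipped_empty_input_rejected(self, caplog):
        text = "!gaf-version: 2.1\nshort\trow\n"
        with pytest.raises(ValueError):
            read_gaf(io.StringIO(text))


class TestReadInteractionTable:
    def test_dedup_orientation_and_self_pairs(self):
        text = "a\tb\nb\ta\na\tc\na\ta\n"
        net = read_interaction_table(io.StringIO(text))
        assert net.pairs == {("a", "b"), ("a", "c")}

    def test_restriction_to_corpus_universe(self):
        text = "a\tb\na\tc\nb\tc\n"
        net = read_interaction_table(io.StringIO(text), restrict_to={"a", "b"})
        assert net.pairs == {("a", "b")}

    def test_configurable_columns(self):
        text = "x\ta\tb\nx\tb\tc\n"
        net = read_interaction_table(io.StringIO(text), col_a=1, col_b=2)
        assert net.pairs == {("a", "b"), ("b", "c")}

    def test_degrees_count_absent_entities_as_zero(self):
        net = InteractionSet.from_pairs([("a", "b"), ("a", "c")])
        assert net.degrees(["a", "b", "z"]) == {"a": 2, "b": 1, "z": 0}


def _matrix_from_scores(scores: dict[tuple[str, str], float]):
    ids = sorted({e for pair in scores for e in pair})
    v = np.zeros((len(ids), len(ids)))
    idx = {e: i for i, e in enumerate(ids)}
    for (a, b), s in scores.items():
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = s
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(ids, v, MeasureSpec.parse("gic"))


def _auc_oracle(scores, labels):
    """Exhaustive positive-vs-negative pair comparison with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_example_value(self):
        # positives score {0.9, 0.4}, negatives {0.8, 0.1}:
        # three of four positive-negative comparisons won -> AUC 3/4
        assert _auc_oracle([0.9, 0.4, 0.8, 0.1], [True, True, False, False]) == 0.75

    def test_four_pair_hand_example(self):
        m = _matrix_from_scores(
            {("a", "b"): 0.9, ("c", "d"): 0.4, ("a", "c"): 0.8, ("b", "d"): 0.1,
             ("a", "d"): 0.0, ("b", "c"): 0.0}
        )
        positives = InteractionSet.from_pairs([("a", "b"), ("c", "d")])
        # restrict attention to the four scored pairs by checking the oracle too
        scores = [0.9, 0.8, 0.0, 0.4, 0.1, 0.0]
        labels = [True, False, False, True, False, False]
        result = roc_auc(m, positives)
        assert result.auc == pytest.approx(_auc_oracle(scores, labels))
        assert result.fpr[0] == 0.0 and result.tpr[0] == 0.0
        assert result.fpr[-1] == 1.0 and result.tpr[-1] == 1.0
        assert (np.diff(result.fpr) >= 0).all() and (np.diff(result.tpr) >= 0).all()
        # trapezoidal area of the curve equals the rank-based AUC
        assert np.trapezoid(result.tpr, result.fpr) == pytest.approx(result.auc)

    def test_perfect_separation(self):
        m = _matrix_from_scores({("a", "b"): 0.9, ("a", "c"): 0.1, ("b", "c"): 0.2})
        assert roc_auc(m, InteractionSet.from_pairs([("a", "b")])).auc == 1.0

    def test_no_positives_in_universe_raises(self):
        m = _matrix_from_scores({("a", "b"): 0.5})
        with pytest.raises(ValueError):
            roc_auc(m, InteractionSet.from_pairs([("x", "y")]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 15  # 105 pairs
        ids = [f"g{i}" for i in range(n)]
        v = rng.random((n, n))
        v = (v + v.T) / 2
        # quantize to force heavy ties, the hard case for rank AUC
        v = np.round(v, 1)
        m = SimilarityMatrix(ids, v, MeasureSpec.parse("gic"))
        all_pairs = list(itertools.combinations(ids, 2))
        chosen = rng.choice(len(all_pairs), size=20, replace=False)
        positives = InteractionSet.from_pairs([all_pairs[i] for i in chosen])
        scores = [m.loc(a, b) for a, b in all_pairs]
        labels = [(a, b) in positives for a, b in all_pairs]
        assert roc_auc(m, positives).auc == pytest.approx(_auc_oracle(scores, labels))

    def test_random_labels_give_null_auc(self):
        rng = np.random.default_rng(3)
        n = 40
        ids = [f"g{i}" for i in range(n)]
        v = rng.random((n, n))
        v = (v + v.T) / 2
        m = SimilarityMatrix(ids, v, MeasureSpec.parse("gic"))
        all_pairs = list(itertools.combinations(ids, 2))
        chosen = rng.choice(len(all_pairs), size=150, replace=False)
        positives = InteractionSet.from_pairs([all_pairs[i] for i in chosen])
        n_pos, n_neg = 150, len(all_pairs) - 150
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(roc_auc(m, positives).auc - 0.5) < 3 * se


class TestPermutationPvalue:
    def test_informative_scores_give_small_p(self):
        g = generate_layered_dag(121, seed=0)
        ic = compute_intrinsic_ic(g)
        corpus = annotate_by_size(g, range(1, 8), 6, seed=1)
        m = similarity_matrix(corpus, MeasureSpec.parse("gic"), g, ic)
        # positives = the most similar pairs: AUC 1, p at the permutation floor
        iu, ju = np.triu_indices(len(m.entity_ids), k=1)
        order = np.argsort(m.values[iu, ju])[::-1][:30]
        ids = m.entity_ids
        positives = InteractionSet.from_pairs(
            [(ids[iu[k]], ids[ju[k]]) for k in order]
        )
        auc, p = auc_permutation_pvalue(m, positives, n_permutations=99, seed=5)
        assert auc > 0.95  # ties among top-scoring pairs can shave a little
        assert p <= 0.05


class TestAnnotationDegreeCorrelation:
    def test_perfectly_coupled_counts(self):
        corpus = AnnotationCorpus({"a": {"c1"}, "b": {"c1", "c2"}, "c": {"c1", "c2", "c3"}})
        net = InteractionSet.from_pairs(
            [("a", "b"), ("a", "c"), ("b", "c")]
        )
        # degrees all 2 -> constant, undefined correlation
        with pytest.raises(ValueError):
            annotation_degree_correlation(corpus, net)

    def test_hand_built_network(self):
        corpus = AnnotationCorpus(
            {"a": {"c1"}, "b": {"c1", "c2"}, "c": {"c1", "c2", "c3"}, "d": {"c1", "c2", "c3", "c4"}}
        )
        net = InteractionSet.from_pairs([("c", "d"), ("b", "d"), ("a", "d")])
        r = annotation_degree_correlation(corpus, net)
        sizes = np.array([1, 2, 3, 4])
        degrees = np.array([1, 1, 1, 3])
        expected = np.corrcoef(sizes, degrees)[0, 1]
        assert r.pearson == pytest.approx(expected)


class TestBiasExperiment:
    def test_deterministic_and_idempotent_in_distribution(self):
        g = generate_layered_dag(364, seed=0)
        ic = compute_intrinsic_ic(g)
        corpus = annotate_by_size(g, range(1, 11), 5, seed=1)
        from ontosim import random_interactions

        net = random_interactions(corpus, 200, size_bias=0.7, hub_sigma=1.0, seed=2)
        real1, rand1 = bias_experiment(corpus, g, ic, net, MeasureSpec.parse("gic"), seed=3)
        real2, rand2 = bias_experiment(corpus, g, ic, net, MeasureSpec.parse("gic"), seed=3)
        assert (real1.auc, rand1.auc) == (real2.auc, rand2.auc)
        # shuffling an already-shuffled corpus moves the AUC only within noise
        from ontosim import shuffle_annotations

        shuffled = shuffle_annotations(corpus, g, seed=4)
        _, rand_twice = bias_experiment(
            shuffled, g, ic, net, MeasureSpec.parse("gic"), seed=5
        )
        assert abs(rand_twice.auc - rand1.auc) < 0.1
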