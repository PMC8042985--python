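import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from linkbench import (
    CandidatePairSet,
    ConfusionCounts,
    Graph,
    IndexConfig,
    aupr,
    auroc,
    classify_topk,
    evaluate_model,
    expand_biadjacency,
    f1,
    fpr,
    friedman_rank,
    holdout_split,
    kfold_split,
    precision,
    recall,
    sample_negatives,
)
from linkbench.evaluation import EvaluationSplit, evaluate_scores

from conftest import er_graph
from oracles import auroc_exhaustive


class TestSplits:
    def test_g1_two_folds(self, G1):
        splits = kfold_split(G1, folds=2, seed=42)
        assert [len(s.test_edges) for s in splits] == [2, 2]
        assert splits[0].test_edges | splits[1].test_edges == G1.edges
        assert not splits[0].test_edges & splits[1].test_edges

    def test_folds_partition_edges(self):
        g = er_graph(25, 0.2, 0)
        splits = kfold_split(g, folds=5, seed=7)
        union = set()
        for s in splits:
            assert not union & s.test_edges
            union |= s.test_edges
            assert s.train_edges == g.edges - s.test_edges
        assert union == g.edges

    def test_determinism(self):
        g = er_graph(25, 0.2, 1)
        a = kfold_split(g, folds=5, seed=3)
        b = kfold_split(g, folds=5, seed=3)
        for sa, sb in zip(a, b):
            assert sa.test_edges == sb.test_edges
            assert sa.test_negatives == sb.test_negatives
            assert sa.train_negatives == sb.train_negatives

    def test_too_many_folds(self, G1):
        with pytest.raises(ValueError):
            kfold_split(G1, folds=5)

    def test_negatives_disjoint_from_edges(self):
        g = er_graph(30, 0.15, 5)
        for s in kfold_split(g, folds=4, seed=9):
            negs = set(s.test_negatives) | set(s.train_negatives)
            assert not negs & g.edges
            assert not set(s.test_negatives) & set(s.train_negatives)

    def test_holdout_fraction(self):
        g = er_graph(30, 0.2, 2)
        s = holdout_split(g, test_fraction=0.1, seed=0)
        assert len(s.test_edges) == round(0.1 * g.m)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            EvaluationSplit(
                train_edges={(0, 1)}, test_edges={(0, 1)},
                train_negatives=[], test_negatives=[], fold_id=0, seed=0,
            )


class TestNegativeSampling:
    def test_g1_exhaustive(self, G1):
        negs = sample_negatives(G1, 2, seed=0)
        assert set(negs) == {
            (G1.index_map["1"], G1.index_map["4"]),
            (G1.index_map["2"], G1.index_map["4"]),
        }

    def test_k2_no_non_edges(self, K2):
        with pytest.raises(ValueError, match="non-edges"):
            sample_negatives(K2, 1)

    def test_bipartite_cross_partition_only(self, tmp_path):
        f = tmp_path / "b.txt"
        f.write_text("d1 t1\nd1 t2\nd2 t1\n")
        g = expand_biadjacency(__import__("linkbench").read_bipartite_edge_list(f))
        negs = sample_negatives(g, 1, seed=0)
        (pair,) = negs
        labels = {g.node_labels[pair[0]], g.node_labels[pair[1]]}
        assert labels == {"d2", "t2"}


class TestPointMetrics:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(8, 2, 0, 0), 0.8),
            (ConfusionCounts(0, 0, 3, 1), 0.0),
            (ConfusionCounts(5, 0, 0, 0), 1.0),
        ],
    )
    def test_precision(self, c, expected):
        assert precision(c) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(8, 0, 2, 0), 0.8),
            (ConfusionCounts(3, 0, 0, 0), 1.0),
            (ConfusionCounts(0, 0, 4, 0), 0.0),
        ],
    )
    def test_recall(self, c, expected):
        assert recall(c) == pytest.approx(expected)

    def test_f1_conventions(self):
        assert f1(0.8, 0.8, "standard") == pytest.approx(0.8)
        assert f1(0.8, 0.8, "as_printed") == pytest.approx(0.4)
        assert f1(1.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            f1(0.5, 0.5, "median")

    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(0, 2, 0, 8), 0.2),
            (ConfusionCounts(0, 0, 0, 8), 0.0),
            (ConfusionCounts(0, 3, 0, 0), 1.0),
        ],
    )
    def test_fpr(self, c, expected):
        assert fpr(c) == pytest.approx(expected)


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_counted(self):
        assert auroc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_exhaustive_oracle_200_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                auroc_exhaustive(scores, labels), abs=1e-12
            )

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=4, max_size=30, unique=True),
           st.data())
    def test_complement_property_tie_free(self, raw, data):
        scores = np.array(raw, dtype=float)
        labels = np.array(
            data.draw(st.lists(st.booleans(), min_size=len(raw), max_size=len(raw)))
        )
        if labels.sum() in (0, len(labels)):
            labels[0] = ~labels[0]
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)


class TestAUPR:
    def test_perfect(self):
        assert aupr([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_single_top_ranked_positive(self):
        assert aupr([0.9, 0.5, 0.1], [1, 0, 0]) == 1.0

    def test_hand_ranked(self):
        assert aupr([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(5 / 6)

    def test_constant_scorer_gives_prevalence(self):
        assert aupr([0.5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                labels[0] = 1 - labels[0]
            assert aupr(scores, labels) == pytest.approx(
                average_precision_score(labels, scores)
            )


class TestClassifyTopK:
    def test_perfect_ranking(self):
        labels = np.array([1, 1, 0, 0])
        c = classify_topk(np.array([0.9, 0.8, 0.2, 0.1]), labels)
        assert (c.tp, c.fp) == (2, 0)
        assert f1(precision(c), recall(c)) == 1.0

    def test_inverted_ranking(self):
        c = classify_topk(np.array([0.1, 0.2, 0.8, 0.9]), [1, 1, 0, 0])
        assert c.tp == 0

    def test_sort_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.random(40)
            labels = rng.integers(0, 2, 40).astype(bool)
            k = int(labels.sum()) or 1
            c = classify_topk(scores, labels, k=k)
            top = np.argsort(-scores, kind="stable")[:k]
            assert c.tp == int(labels[top].sum())


class TestEvaluateModel:
    def test_oracle_scorer_is_perfect(self):
        g = er_graph(30, 0.2, 4)
        splits = kfold_split(g, folds=3, seed=1)
        for s in splits:
            n_pos, n_neg = len(s.test_edges), len(s.test_negatives)
            scores = np.r_[np.ones(n_pos), np.zeros(n_neg)]
            labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
            a, p, f = evaluate_scores(scores, labels)
            assert (a, p, f) == (1.0, 1.0, 1.0)

    def test_constant_scorer_half_auroc(self):
        a, _, _ = evaluate_scores(np.full(20, 0.3), np.r_[np.ones(10), np.zeros(10)])
        assert a == 0.5

    def test_registered_model_end_to_end(self):
        g = er_graph(40, 0.2, 8)
        splits = kfold_split(g, folds=3, seed=2)
        reports = evaluate_model("cn", g, splits, IndexConfig())
        assert len(reports) == 3
        for r in reports:
            assert 0 <= r.auroc <= 1 and 0 <= r.aupr <= 1 and 0 <= r.f1 <= 1

    def test_unknown_model(self, G1):
        from linkbench import UnknownModelError

        with pytest.raises(UnknownModelError, match="prone"):
            evaluate_model("prone", G1, [])


class TestFriedman:
    def test_constant_ordering_closed_form(self):
        E = np.tile([0.1, 0.2, 0.3], (5, 1))
        rt = friedman_rank(E, models=["best", "mid", "worst"])
        np.testing.assert_allclose(rt.mean_rank, [1, 2, 3])
        assert rt.friedman_statistic == pytest.approx(10.0)

    def test_identical_errors(self):
        rt = friedman_rank(np.full((4, 3), 0.25))
        np.testing.assert_allclose(rt.mean_rank, 2.0)
        assert rt.friedman_statistic == 0.0
        assert rt.p_value == 1.0

    def test_scipy_cross_check(self):
        rng = np.random.default_rng(5)
        E = rng.random((8, 4))
        rt = friedman_rank(E)
        stat, p = scipy.stats.friedmanchisquare(*(E[:, j] for j in range(4)))
        assert rt.friedman_statistic == pytest.approx(stat)
        assert rt.p_value == pytest.approx(p)

    def test_permutation_null_agreement(self):
        """Chi-square p within 3 MC standard errors of a permutation null.

        The block count is large (N=500) so the chi-square asymptotics are
        valid; values are continuous so within-block permutation of ranks is
        an exact permutation null for the statistic.
        """
        rng = np.random.default_rng(0)
        N, k, n_perm = 500, 5, 100_000
        E = rng.random((N, k))
        rt = friedman_rank(E)
        count = 0
        for start in range(0, n_perm, 2000):
            b = min(2000, n_perm - start)
            perm_ranks = rng.permuted(
                np.broadcast_to(np.arange(1, k + 1), (b, N, k)).copy(), axis=2
            )
            colsums = perm_ranks.sum(axis=1)
            stats = (
                12.0 / (N * k * (k + 1)) * np.sum(colsums**2, axis=1)
                - 3.0 * N * (k + 1)
            )
            count += int(np.sum(stats >= rt.friedman_statistic - 1e-12))
        p_mc = count / n_perm
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-9) / n_perm)
        assert abs(rt.p_value - p_mc) <= 3 * se

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            friedman_rank(np.array([[0.1, np.nan], [0.2, 0.3]]))
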