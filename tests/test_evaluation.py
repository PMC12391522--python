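import numpy as np
import pytest

from metaharm import (
    RankingResult,
    SplitPlan,
    TrainConfig,
    ValidationError,
    VariableRecord,
    bootstrap_ci,
    mean_confusion_rates,
    per_concept_confusion,
    roc_auc,
    run_evaluation,
    score_summary_by_group,
    top_k_accuracy,
)


def brute_force_auc(scores, labels):
    """O(n^2) Mann–Whitney: P(pos > neg) with ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def make_ranking(true_concept, order, scores=None):
    scores = scores or [1.0 - 0.01 * i for i in range(len(order))]
    query = VariableRecord("x", f"q_{true_concept}_{hash(tuple(order)) % 10**6}",
                          "query text", true_concept)
    return RankingResult(query=query, ranked=list(zip(order, scores)))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints(self):
        _, curve = roc_auc([0.9, 0.1, 0.8, 0.3], [1, 0, 1, 0])
        assert curve[0] == (0.0, 0.0) and curve[-1] == (1.0, 1.0)


class TestTopKAccuracy:
    def test_all_correct_at_k1(self):
        rankings = [make_ranking("a", ["a", "b", "c"]) for _ in range(5)]
        assert top_k_accuracy(rankings, 1) == 100.0

    def test_rank_three_of_ten(self):
        order = [f"c{i}" for i in range(10)]
        rankings = [make_ranking("c2", order) for _ in range(4)]
        assert top_k_accuracy(rankings, 5) == 100.0
        assert top_k_accuracy(rankings, 1) == 0.0

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(5)
        concepts = [f"c{i}" for i in range(8)]
        rankings = []
        for i in range(50):
            order = list(rng.permutation(concepts))
            rankings.append(make_ranking(rng.choice(concepts), order))
        for k in (1, 3, 5, 8):
            expected = 100.0 * np.mean(
                [r.query.concept_id in [c for c, _ in r.ranked[:k]] for r in rankings]
            )
            assert top_k_accuracy(rankings, k) == pytest.approx(expected)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(6)
        concepts = [f"c{i}" for i in range(6)]
        rankings = [
            make_ranking(rng.choice(concepts), list(rng.permutation(concepts)))
            for _ in range(30)
        ]
        accs = [top_k_accuracy(rankings, k) for k in range(1, 7)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 100.0

    def test_truth_missing_from_ranking_rejected(self):
        bad = make_ranking("zz", ["a", "b"])
        with pytest.raises(ValidationError, match="absent"):
            top_k_accuracy([bad], 1)


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        lo, hi = bootstrap_ci(lambda x: 42.0, np.arange(50), reps=200, seed=0)
        assert lo == hi == 42.0

    def test_interval_contains_point_estimate_for_mean(self):
        rng = np.random.default_rng(1)
        data = rng.random(300)
        lo, hi = bootstrap_ci(lambda x: float(np.mean(x)), data, reps=500, seed=2)
        assert lo <= data.mean() <= hi
        assert 0.0 <= lo <= hi <= 1.0

    def test_reproducible_given_seed(self):
        data = np.random.default_rng(3).random(100)
        a = bootstrap_ci(lambda x: float(np.mean(x)), data, reps=300, seed=7)
        b = bootstrap_ci(lambda x: float(np.mean(x)), data, reps=300, seed=7)
        assert a == b

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_ci(lambda x: 0.0, np.arange(10), reps=50)

    def test_degenerate_resamples_redrawn(self):
        # tiny data with a rare class: some resamples are single-class and
        # must be redrawn rather than crashing
        scores = np.array([0.9, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        labels = np.array([1, 0, 0, 0, 0, 0, 0, 0])

        def metric(s, y):
            if len(np.unique(y)) < 2:
                raise ValidationError("single class")
            return float(np.mean(s[y == 1]))

        lo, hi = bootstrap_ci(metric, (scores, labels), reps=200, seed=4)
        assert np.isfinite(lo) and np.isfinite(hi)


class TestPerConceptConfusion:
    def test_perfect_classifier(self):
        rankings = [
            make_ranking(c, [c] + [o for o in ("a", "b", "c") if o != c])
            for c in ("a", "b", "c")
            for _ in range(3)
        ]
        rates = per_concept_confusion(rankings)
        for c in ("a", "b", "c"):
            assert rates[c]["ppv"] == 1.0
            assert rates[c]["tpr"] == 1.0
            assert rates[c]["fpr"] == 0.0

    def test_never_predicted_concept_has_absent_ppv(self):
        # truth c twice, but prediction always a
        rankings = [make_ranking("c", ["a", "b", "c"]) for _ in range(2)]
        rates = per_concept_confusion(rankings)
        assert rates["c"]["ppv"] is None
        assert rates["c"]["tpr"] == 0.0

    def test_hand_tallied_three_concept_confusion(self):
        # 4 queries of a (3 -> a, 1 -> b); 3 of b (2 -> b, 1 -> c); 2 of c (2 -> c)
        r = []
        r += [make_ranking("a", ["a", "b", "c"])] * 3 + [make_ranking("a", ["b", "a", "c"])]
        r += [make_ranking("b", ["b", "a", "c"])] * 2 + [make_ranking("b", ["c", "b", "a"])]
        r += [make_ranking("c", ["c", "a", "b"])] * 2
        rates = per_concept_confusion(r)
        # concept a: TP=3 FP=0 FN=1 TN=5
        assert rates["a"]["ppv"] == 1.0
        assert rates["a"]["tpr"] == pytest.approx(3 / 4)
        assert rates["a"]["npv"] == pytest.approx(5 / 6)
        assert rates["a"]["fpr"] == 0.0
        # concept b: TP=2 FP=1 FN=1 TN=5
        assert rates["b"]["ppv"] == pytest.approx(2 / 3)
        assert rates["b"]["tpr"] == pytest.approx(2 / 3)
        assert rates["b"]["fpr"] == pytest.approx(1 / 6)
        means = mean_confusion_rates(rates)
        assert 0 <= means["fpr"][0] <= means["tpr"][0] <= 1

    def test_score_summary_separates_matches(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        groups = ["vitals", "vitals", "vitals", "diet"]
        summary = score_summary_by_group(scores, labels, groups, groups)
        v = summary["vitals"]
        assert v["match"][1] > v["nonmatch"][1]  # median separation
        assert summary["diet"]["match"] is None


class TestRunEvaluation:
    def test_combined_report_fully_populated(self, small_world):
        report, scorer = run_evaluation(
            small_world.corpus, small_world.provider, SplitPlan(seed=0),
            model="baseline", bootstrap_reps=150, seed=9,
        )
        assert 0.0 <= report.auc <= 1.0
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
        a1 = report.top_k[1]["accuracy"]
        a5 = report.top_k[5]["accuracy"]
        assert a1 <= a5 <= 100.0
        assert report.per_concept and report.per_group_score_summary
        assert report.n_pairs_test > 0 and report.n_queries > 0

    def test_loco_queries_all_from_held_out_cohort(self, small_world):
        held = small_world.corpus.cohorts[0]
        plan = SplitPlan(
            strategy="leave_one_cohort_out", held_out_cohort=held, seed=0
        )
        report, _ = run_evaluation(
            small_world.corpus, small_world.provider, plan,
            model="baseline", bootstrap_reps=150, seed=9,
        )
        assert report.strategy == "leave_one_cohort_out"
        assert report.n_queries > 0

    def test_same_seed_reports_identical(self, small_world):
        kwargs = dict(model="fcn", bootstrap_reps=150, seed=4,
                      train_config=TrainConfig(seed=3, max_epochs=8, patience=3,
                                               hidden_dim=16))
        a, _ = run_evaluation(
            small_world.corpus, small_world.provider, SplitPlan(seed=0), **kwargs
        )
        b, _ = run_evaluation(
            small_world.corpus, small_world.provider, SplitPlan(seed=0), **kwargs
        )
        assert a.to_json() == b.to_json()
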