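"""Metric suite: worked examples, oracle equivalence, baselines."""

import itertools

import numpy as np
import pytest

import sdmfuse as sf
from sdmfuse.evaluation import (ScoreMatrix, metric_report,
                                mean_average_precision, topk_accuracy)


def brute_force_auc(scores, labels):
    """Pairwise-counting oracle: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    if not pos or not neg:
        return float("nan")
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAucRoc:
    def test_perfect_separation(self):
        assert sf.auc_roc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert sf.auc_roc([0.3] * 10, [1, 0] * 5) == 0.5

    def test_hand_example_three_quarters(self):
        assert sf.auc_roc([0.8, 0.7, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_undefined(self):
        assert np.isnan(sf.auc_roc([0.1, 0.2], [1, 1]))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 50)
            scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            expected = brute_force_auc(scores, labels)
            got = sf.auc_roc(scores, labels)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestAucPrc:
    def test_perfect_ranking(self):
        assert sf.auc_prc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        assert sf.auc_prc([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1]) == 0.25

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(1)
        n, prevalence = 20_000, 0.15
        labels = rng.random(n) < prevalence
        scores = rng.random(n)
        assert sf.auc_prc(scores, labels) == pytest.approx(prevalence,
                                                           rel=0.1)

    def test_no_positives_undefined(self):
        assert np.isnan(sf.auc_prc([0.1, 0.2], [0, 0]))


class TestThresholdMetrics:
    def test_all_correct(self):
        sm = ScoreMatrix(np.full((3, 2), 0.9), np.ones((3, 2)))
        m = sf.threshold_metrics(sm, 0.5)
        assert np.all(m["species_precision"] == 1)
        assert np.all(m["obs_recall"] == 1)
        assert m["presence_accuracy"] == 1.0

    def test_all_below_threshold(self):
        sm = ScoreMatrix(np.full((3, 2), 0.1), np.ones((3, 2)))
        m = sf.threshold_metrics(sm, 0.5)
        assert np.all(m["species_recall"] == 0)
        assert m["presence_accuracy"] == 0.0

    def test_worked_two_by_two(self):
        sm = ScoreMatrix(np.array([[0.6, 0.2], [0.4, 0.7]]),
                         np.array([[1, 0], [1, 1]]))
        m = sf.threshold_metrics(sm, 0.5)
        np.testing.assert_allclose(m["obs_recall"], [1.0, 0.5])
        assert m["presence_accuracy"] == pytest.approx(2 / 3)

    def test_no_predicted_positives_precision_zero(self):
        sm = ScoreMatrix(np.full((4, 1), 0.2), np.array([[1], [0], [1], [0]]))
        m = sf.threshold_metrics(sm, 0.5)
        assert m["species_precision"][0] == 0.0


class TestTopK:
    def test_argmax_at_k1(self):
        sm = ScoreMatrix(np.array([[0.1, 0.9, 0.3]]), np.array([[0, 1, 0]]))
        assert topk_accuracy(sm, 1)["obs_mean"] == 1.0

    def test_hand_ranking_half_hit(self):
        sm = ScoreMatrix(np.array([[0.9, 0.8, 0.7, 0.6, 0.5]]),
                         np.array([[1, 0, 0, 0, 1]]))
        assert topk_accuracy(sm, 2)["obs_mean"] == 0.5

    def test_ties_break_by_species_index(self):
        sm = ScoreMatrix(np.array([[0.5, 0.5, 0.5]]), np.array([[0, 0, 1]]))
        # all tied: top-1 must pick species 0, so the true species misses
        assert topk_accuracy(sm, 1)["obs_mean"] == 0.0
        assert topk_accuracy(sm, 3)["obs_mean"] == 1.0

    def test_monotone_in_k_and_one_at_s(self):
        rng = np.random.default_rng(2)
        sm = ScoreMatrix(rng.random((20, 12)),
                         rng.random((20, 12)) < 0.3)
        sm.targets[:, 0] = True
        values = [topk_accuracy(sm, k)["obs_mean"] for k in range(1, 13)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == 1.0


class TestMeanAveragePrecision:
    def test_perfect_and_reversed(self):
        targets = np.array([[1], [0], [0], [0]])
        assert mean_average_precision(
            ScoreMatrix(np.array([[0.9], [0.3], [0.2], [0.1]]), targets)) == 1.0
        assert mean_average_precision(
            ScoreMatrix(np.array([[0.1], [0.3], [0.4], [0.9]]), targets)) == 0.25

    def test_equals_mean_of_per_species_ap(self):
        rng = np.random.default_rng(3)
        sm = ScoreMatrix(rng.random((30, 5)), rng.random((30, 5)) < 0.4)
        per = [sf.auc_prc(sm.scores[:, s], sm.targets[:, s]) for s in range(5)]
        per = [v for v in per if not np.isnan(v)]
        assert mean_average_precision(sm) == pytest.approx(np.mean(per))


class TestBaselines:
    def _targets(self, n=400, s=60, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.random((n, s)) < 0.15
        t[~t.any(axis=1), 0] = True
        return t

    def test_random_baseline_centers_on_half(self):
        report = sf.random_baseline_report(self._targets(), trials=5, seed=0)
        assert report.aggregates["auc_roc_spp_median"] == pytest.approx(0.5,
                                                                       abs=0.02)
        assert report.aggregates["recall_obs_median"] == pytest.approx(0.5,
                                                                      abs=0.1)

    def test_single_trial_deterministic(self):
        t = self._targets()
        a = sf.random_baseline_report(t, trials=1, seed=4)
        b = sf.random_baseline_report(t, trials=1, seed=4)
        assert a.aggregates == b.aggregates

    def test_frequency_rescaling_endpoints(self):
        sm = sf.frequency_baseline_scores(np.array([10, 30]), n_obs=3)
        np.testing.assert_allclose(sm.scores[0], [0.001, 1.0])
        assert sm.scores.shape == (3, 2)

    def test_frequency_constant_columns_auc_exactly_half(self):
        targets = self._targets(n=200, s=10, seed=5)
        counts = np.arange(1, 11)
        sm = sf.frequency_baseline_scores(counts, n_obs=200, targets=targets)
        aucs = [sf.auc_roc(sm.scores[:, s], sm.targets[:, s])
                for s in range(10)]
        assert all(a == 0.5 for a in aucs)


class TestMetricReport:
    def test_scores_equal_targets_all_binary_metrics_one(self):
        rng = np.random.default_rng(6)
        targets = rng.random((50, 8)) < 0.3
        targets[~targets.any(axis=1), 0] = True
        scores = np.where(targets, 0.999, 0.001)
        report = metric_report(ScoreMatrix(scores, targets))
        for key in ("auc_roc_spp_median", "precision_spp_median",
                    "recall_spp_median", "f1_spp_median",
                    "presence_accuracy"):
            assert report.aggregates[key] == 1.0

    def test_rates_in_unit_interval_and_median_inside_iqr(self):
        rng = np.random.default_rng(7)
        targets = rng.random((80, 15)) < 0.2
        targets[~targets.any(axis=1), 0] = True
        report = metric_report(ScoreMatrix(rng.random((80, 15)), targets))
        for name in ("auc_roc", "precision", "recall", "f1"):
            med = report.aggregates[f"{name}_spp_median"]
            q1 = report.aggregates[f"{name}_spp_q1"]
            q3 = report.aggregates[f"{name}_spp_q3"]
            assert 0 <= q1 <= med <= q3 <= 1
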