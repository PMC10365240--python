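"""Tests for nested cross-validation, voting, and metric computation."""

import math

import numpy as np
import pytest

from smfcnet import (
    CVPlan,
    balanced_accuracy,
    compute_metrics,
    ensemble_accuracy,
    majority_vote,
    nested_cv,
)
from conftest import make_probe_dataset


class TestMajorityVote:
    def test_examples(self):
        assert majority_vote([1] * 13 + [0] * 12) == 1
        assert majority_vote([0] * 25) == 0

    def test_even_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote([0, 1])

    def test_matches_brute_force_count(self, rng):
        for _ in range(1000):
            votes = rng.integers(0, 2, size=25)
            expected = 1 if votes.sum() > 12 else 0
            assert majority_vote(votes) == expected


class TestMetrics:
    def test_hand_computed_confusion_table(self):
        m = compute_metrics(tp=3, tn=4, fp=1, fn=2)
        assert m["ACC"] == pytest.approx(0.7)
        assert m["SEN"] == pytest.approx(0.6)
        assert m["SPE"] == pytest.approx(0.8)
        assert m["BAC"] == pytest.approx(0.7)
        assert m["PPV"] == pytest.approx(0.75)
        assert m["F1"] == pytest.approx(2 / 3)

    def test_bac_identity_on_published_operating_point(self):
        # SEN 74.97%, SPE 80.86% -> BAC 77.92% (to the printed precision)
        # one unit in the last printed decimal place
        assert balanced_accuracy(74.97, 80.86) == pytest.approx(77.92, abs=0.01)

    def test_all_correct_gives_ones(self):
        m = compute_metrics(tp=5, tn=5, fp=0, fn=0,
                            scores=[.9] * 5 + [.1] * 5, labels=[1] * 5 + [0] * 5)
        for k in ("ACC", "SEN", "SPE", "BAC", "AUC", "F1", "PPV"):
            assert m[k] == pytest.approx(1.0)

    def test_zero_denominator_reported_as_undefined(self):
        m = compute_metrics(tp=0, tn=5, fp=0, fn=0)
        assert math.isnan(m["SEN"]) and math.isnan(m["PPV"])
        assert m["SPE"] == 1.0

    def test_negative_or_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)

    def test_auc_rank_statistic(self, rng):
        labels = np.array([0, 1] * 100)
        perfect = np.where(labels == 1, 0.9, 0.1) + rng.random(200) * 0.05
        assert compute_metrics(100, 100, 0, 0, perfect, labels)["AUC"] == 1.0
        random_scores = rng.random(200)
        auc = compute_metrics(50, 50, 50, 50, random_scores, labels)["AUC"]
        assert abs(auc - 0.5) < 0.12  # Monte-Carlo tolerance at n=200

    def test_metrics_invariant_to_subject_order(self, rng):
        labels = rng.integers(0, 2, 50)
        scores = rng.random(50)
        perm = rng.permutation(50)
        a = compute_metrics(10, 10, 5, 5, scores, labels)["AUC"]
        b = compute_metrics(10, 10, 5, 5, scores[perm], labels[perm])["AUC"]
        assert a == pytest.approx(b)


class TestCVPlan:
    def test_defaults_give_25_base_classifiers(self):
        assert CVPlan().n_base_classifiers == 25

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            CVPlan(outer_folds=1)
        with pytest.raises(ValueError):
            CVPlan(validation_fraction=0.0)


class TestNestedCV:
    @pytest.fixture
    def small_result(self, rng, probe_factory):
        X, y = make_probe_dataset(rng, n=40)
        plan = CVPlan(outer_repetitions=2, seed=5)
        return nested_cv(X, y, plan, probe_factory), X, y

    def test_each_fold_retains_25_base_classifiers(self, small_result):
        result, _, _ = small_result
        for rep in result.ensembles:
            assert len(rep) == 5
            for fe in rep:
                assert len(fe.classifiers) == 25

    def test_no_test_subject_seen_in_training(self, small_result):
        result, X, y = small_result
        for rep in result.ensembles:
            seen = np.concatenate([fe.test_idx for fe in rep])
            assert sorted(seen) == list(range(len(y)))  # exact partition
            for fe in rep:
                assert np.intersect1d(fe.train_idx, fe.test_idx).size == 0

    def test_perfectly_separable_data_scores_100_percent(self, small_result):
        result, X, y = small_result
        assert np.all(result.report.per_repetition["ACC"] == 1.0)
        assert ensemble_accuracy(result, X, y) == 1.0

    def test_single_class_and_tiny_class_rejected(self, rng, probe_factory):
        X, y = make_probe_dataset(rng, n=40)
        with pytest.raises(ValueError, match="two classes"):
            nested_cv(X, np.zeros_like(y), CVPlan(), probe_factory)
        y_skewed = y.copy()
        y_skewed[y == 1] = 0
        y_skewed[:3] = 1
        with pytest.raises(ValueError, match="stratify"):
            nested_cv(X, y_skewed, CVPlan(), probe_factory)

    def test_even_voter_plans_rejected(self, rng, probe_factory):
        X, y = make_probe_dataset(rng, n=40)
        with pytest.raises(ValueError, match="odd"):
            nested_cv(X, y, CVPlan(inner_folds=2, inner_repetitions=2),
                      probe_factory)

    def test_hyperparameter_grid_selects_discriminative_edge(self, rng, probe_factory):
        # grid search over which edge the probe uses: only (0, 1) separates
        X, y = make_probe_dataset(rng, n=40, edge=(0, 1))
        plan = CVPlan(outer_repetitions=1, inner_repetitions=1, seed=3)
        result = nested_cv(X, y, plan, probe_factory,
                           param_grid={"edge": [(2, 3), (0, 1)]})
        for fe in result.ensembles[0]:
            assert fe.best_params == {"edge": (0, 1)}

    def test_mean_std_aggregation(self, small_result):
        result, _, _ = small_result
        rep = result.report.per_repetition
        assert len(rep) == 2
        assert result.report.mean["ACC"] == pytest.approx(rep["ACC"].mean())
        assert result.report.std["ACC"] == pytest.approx(rep["ACC"].std(ddof=1))
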