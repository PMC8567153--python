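"""Benchmark harness: native baselines, ROC properties, cross-validation."""

import numpy as np
import pytest

import imuwrist as iw
from imuwrist.bench import BASELINE_NAMES, BenchmarkTable, EvalResult, make_classifier
from imuwrist.errors import ConfigError, InvalidParameterError, UndefinedAUCError
from imuwrist.features import LabeledDataset


def random_dataset(n1, n0, n_features=20, seed=0):
    """Features independent of labels: the permutation null."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n1 + n0, n_features))
    y = np.array([1] * n1 + [0] * n0)
    perm = rng.permutation(len(y))
    return LabeledDataset(X=X[perm], y=y[perm])


class TestZeroR:
    def test_predicts_majority(self):
        model = iw.ZeroR().fit(np.zeros((5, 2)), [1, 1, 1, 0, 0])
        assert np.all(model.predict(np.zeros((3, 2))) == 1)

    def test_tie_prefers_label_zero(self):
        model = iw.ZeroR().fit(np.zeros((4, 2)), [0, 0, 1, 1])
        assert np.all(model.predict(np.zeros((2, 2))) == 0)

    def test_single_class_is_perfect(self):
        model = iw.ZeroR().fit(np.zeros((4, 2)), [1, 1, 1, 1])
        assert np.all(model.predict(np.zeros((4, 2))) == 1)

    def test_empty_training_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            iw.ZeroR().fit(np.zeros((0, 2)), [])


class TestOneR:
    def test_separable_feature_is_found_and_perfect(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.normal(size=(n, 5))
        X[:, 3] = y * 10.0 + rng.normal(0, 0.1, size=n)  # clean separator
        model = iw.OneR().fit(X, y)
        assert model.feature_ == 3
        assert np.mean(model.predict(X) == y) == 1.0

    def test_tie_prefers_lower_index(self):
        y = np.array([0, 0, 0, 1, 1, 1] * 4)
        x = y * 1.0
        X = np.column_stack([x, x])
        model = iw.OneR().fit(X, y)
        assert model.feature_ == 0

    def test_null_features_score_near_baseline(self):
        # permutation oracle: with labels independent of every feature,
        # cross-validated OneR cannot beat the majority-class baseline
        data = random_dataset(500, 500, n_features=50, seed=1)
        table = iw.run_cv(data, ["ZeroR", "OneR"], iw.CVConfig(seed=1))
        zeror = table["ZeroR"].accuracy
        oner = table["OneR"].accuracy
        assert abs(oner - zeror) <= 5.0

    def test_all_constant_features_fall_back_to_majority(self):
        X = np.ones((10, 3))
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0])
        model = iw.OneR().fit(X, y)
        assert model.feature_ is None
        assert np.all(model.predict(X) == 1)


class TestRocPoints:
    def test_perfect_scores(self):
        fpr, tpr, auc = iw.roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=1000)
        labels = rng.integers(0, 2, size=1000)
        _, _, auc = iw.roc_points(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(0, 1, 300) > 0).astype(int)
        _, _, auc = iw.roc_points(scores, labels)
        _, _, auc_neg = iw.roc_points(-scores, labels)
        assert auc_neg == pytest.approx(1.0 - auc, abs=1e-12)

    def test_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(4)
        fpr, tpr, _ = iw.roc_points(rng.normal(size=200),
                                    rng.integers(0, 2, size=200))
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            iw.roc_points([0.1, 0.2], [1, 1])


class TestRunCV:
    def test_zeror_equals_majority_fraction_exactly(self):
        data = random_dataset(171, 149, seed=5)
        table = iw.run_cv(data, ["ZeroR"], iw.CVConfig(k=10, seed=0))
        assert table["ZeroR"].accuracy == pytest.approx(100 * 171 / 320)
        assert round(table["ZeroR"].accuracy, 2) == 53.44
        assert table["ZeroR"].auc == pytest.approx(0.5, abs=0.05)

    def test_deterministic_under_fixed_seed(self, small_cohort_dataset):
        cv = iw.CVConfig(k=4, seed=9)
        t1 = iw.run_cv(small_cohort_dataset, ["ZeroR", "OneR", "C45Tree"], cv)
        t2 = iw.run_cv(small_cohort_dataset, ["ZeroR", "OneR", "C45Tree"], cv)
        for name in t1.rows:
            assert t1[name].accuracy == t2[name].accuracy
            assert t1[name].auc == t2[name].auc

    def test_separated_cohort_tree_ensemble_beats_ninety(self, small_cohort_dataset):
        cv = iw.CVConfig(k=4, seed=0)
        table = iw.run_cv(small_cohort_dataset, ["ZeroR", "RandomForest"], cv)
        assert table["RandomForest"].accuracy > 90.0
        assert table["ZeroR"].accuracy == pytest.approx(50.0)

    def test_k_larger_than_dataset_rejected(self):
        data = random_dataset(3, 3)
        with pytest.raises(ConfigError):
            iw.run_cv(data, ["ZeroR"], iw.CVConfig(k=10))

    def test_unknown_classifier_rejected(self):
        data = random_dataset(10, 10)
        with pytest.raises(ConfigError):
            iw.run_cv(data, ["QuantumForest"], iw.CVConfig(k=2))

    def test_per_fold_accuracies_reported(self):
        data = random_dataset(30, 30, seed=6)
        table = iw.run_cv(data, ["ZeroR"], iw.CVConfig(k=5, seed=0))
        assert len(table["ZeroR"].per_fold) == 5

    def test_every_named_classifier_constructible(self):
        for name in iw.bench.CLASSIFIER_NAMES:
            assert make_classifier(iw.ClassifierSpec(name)) is not None


class TestSummarize:
    @staticmethod
    def table_from_accuracies(pairs):
        rows = {name: EvalResult(accuracy=acc, auc=auc)
                for name, acc, auc in pairs}
        return BenchmarkTable(rows=rows)

    def test_average_row_excludes_baseline(self):
        table = self.table_from_accuracies([
            ("ZeroR", 53.44, 0.494), ("OneR", 80.0, 0.8), ("KNN", 90.0, 0.9),
        ])
        out = iw.summarize(table)
        avg = out[out.classifier == "Average"].iloc[0]
        assert avg.accuracy == pytest.approx(85.0)
        assert avg.auc == pytest.approx(0.85)

    def test_single_row_average_equals_row(self):
        table = self.table_from_accuracies([("KNN", 82.07, 0.89)])
        out = iw.summarize(table)
        avg = out[out.classifier == "Average"].iloc[0]
        assert avg.accuracy == 82.07 and avg.auc == 0.89

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidParameterError):
            iw.summarize(BenchmarkTable(rows={}))
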