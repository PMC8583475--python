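"""Metrics, CV splitting, the 5x2cv paired t-test, permutation importance."""

import numpy as np
import pytest

from ordcrash import (
    compute_metrics,
    critical_value,
    five_two_cv_ttest,
    permutation_importance,
    stratified_cv_811,
)
from ordcrash.evaluation import accuracy, macro_f1


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        report = compute_metrics(y, y, 3)
        np.testing.assert_allclose(report.precision, 1.0)
        np.testing.assert_allclose(report.recall, 1.0)
        assert report.macro_f1 == 1.0

    def test_never_predicted_class_scores_zero(self, caplog):
        y_true = np.array([1, 2, 3, 3])
        y_pred = np.array([1, 2, 2, 1])  # class 3 never predicted
        with caplog.at_level("WARNING", logger="ordcrash.evaluation"):
            report = compute_metrics(y_true, y_pred, 3)
        assert report.precision[2] == 0.0 and report.recall[2] == 0.0 and report.f1[2] == 0.0

    def test_hand_computed_confusion_matrix(self):
        """Counts (8,2,0 / 1,6,3 / 0,2,4): metrics from the count formulas."""
        y_true = np.repeat([1, 2, 3], [10, 10, 6])
        y_pred = np.concatenate(
            [np.repeat([1, 2], [8, 2]), np.repeat([1, 2, 3], [1, 6, 3]), np.repeat([2, 3], [2, 4])]
        )
        report = compute_metrics(y_true, y_pred, 3)
        np.testing.assert_array_equal(report.confusion, [[8, 2, 0], [1, 6, 3], [0, 2, 4]])
        np.testing.assert_allclose(report.precision, [8 / 9, 6 / 10, 4 / 7])
        np.testing.assert_allclose(report.recall, [8 / 10, 6 / 10, 4 / 6])
        expected_f1 = [2 * p * r / (p + r) for p, r in zip(report.precision, report.recall)]
        np.testing.assert_allclose(report.f1, expected_f1)
        assert report.macro_precision == pytest.approx(np.mean(report.precision))

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 2], [1], 2)


class TestStratifiedCV:
    def test_folds_preserve_class_proportions(self, rng):
        labels = np.repeat([1, 2, 3], [700, 250, 50])
        splits = stratified_cv_811(labels, n_folds=10, seed=0)
        for _, _, test in splits:
            counts = np.bincount(labels[test], minlength=4)[1:]
            np.testing.assert_allclose(counts, [70, 25, 5], atol=1)

    def test_rotation_partitions_dataset(self):
        labels = np.repeat([1, 2], [80, 40])
        splits = stratified_cv_811(labels, n_folds=10, seed=1)
        assert len(splits) == 10
        all_test = np.concatenate([te for _, _, te in splits])
        assert sorted(all_test) == list(range(120))
        for tr, cal, te in splits:
            assert not (set(tr) & set(cal) or set(tr) & set(te) or set(cal) & set(te))
            assert len(tr) + len(cal) + len(te) == 120

    def test_same_seed_reproduces_splits(self):
        labels = np.repeat([1, 2], [80, 40])
        a = stratified_cv_811(labels, seed=5)
        b = stratified_cv_811(labels, seed=5)
        for (t1, c1, e1), (t2, c2, e2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_class_too_small_is_an_error(self):
        labels = np.array([1] * 50 + [2] * 5)
        with pytest.raises(ValueError, match="2"):
            stratified_cv_811(labels, n_folds=10)


class _SeededGuess:
    """Learner-free classifier emitting seeded uniform guesses."""

    def __init__(self, salt):
        self.salt = salt

    def __call__(self, X_tr, y_tr, X_te, seed=0):
        rng = np.random.default_rng((seed * 1_000_003 + self.salt) % 2**31)
        return rng.choice(np.unique(y_tr), size=len(X_te))


class TestFiveTwoCV:
    def test_identical_methods_give_t_zero_p_one(self, rng):
        X = rng.standard_normal((80, 3))
        y = rng.integers(1, 3, size=80)
        guess = _SeededGuess(7)
        res = five_two_cv_ttest(guess, guess, X, y, seed=3)
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        np.testing.assert_array_equal(res.deltas, 0.0)

    def test_swapping_methods_negates_t(self, rng):
        X = rng.standard_normal((100, 3))
        y = rng.integers(1, 3, size=100)
        a, b = _SeededGuess(1), _SeededGuess(2)
        r1 = five_two_cv_ttest(a, b, X, y, seed=11)
        r2 = five_two_cv_ttest(b, a, X, y, seed=11)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_reference_distribution_critical_value(self):
        assert round(critical_value(0.95, 5), 3) == 2.571
        res = five_two_cv_ttest(
            _SeededGuess(1), _SeededGuess(2), np.zeros((40, 2)), np.tile([1, 2], 20), seed=0
        )
        assert res.alpha_critical == pytest.approx(critical_value(0.95, 5))

    def test_first_repetition_variant_runs(self, rng):
        X = rng.standard_normal((60, 2))
        y = rng.integers(1, 3, size=60)
        res = five_two_cv_ttest(_SeededGuess(1), _SeededGuess(2), X, y, seed=2, variant="first_repetition")
        assert 0.0 <= res.p_value <= 1.0

    def test_macro_f1_metric_accepted(self, rng):
        X = rng.standard_normal((60, 2))
        y = rng.integers(1, 3, size=60)
        res = five_two_cv_ttest(_SeededGuess(1), _SeededGuess(2), X, y, metric=macro_f1, seed=2)
        assert np.isfinite(res.t_statistic)


class TestPermutationImportance:
    def test_deterministic_feature_ranks_first_and_constant_near_zero(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 400
        features = pd.DataFrame(
            {
                "signal": rng.integers(1, 4, size=n).astype(float),
                "noise": rng.standard_normal(n),
                "constant": np.ones(n),
            }
        )
        y = features["signal"].to_numpy().astype(int)  # label fully determined

        def predict_fn(frame):
            return frame["signal"].round().clip(1, 3).astype(int).to_numpy()

        table = permutation_importance(predict_fn, features, y, n_repeats=10, seed=1)
        assert table.iloc[0]["feature"] == "signal"
        const_row = table[table["feature"] == "constant"].iloc[0]
        assert abs(const_row["importance"]) <= max(2 * const_row["std"], 1e-12)

    def test_shuffling_everything_destroys_the_metric(self, rng):
        import pandas as pd

        y = rng.integers(1, 3, size=300)
        features = pd.DataFrame({"x": y + 0.01 * rng.standard_normal(300)})

        def predict_fn(frame):
            return frame["x"].round().clip(1, 2).astype(int).to_numpy()

        baseline = accuracy(y, predict_fn(features))
        shuffled = features.copy()
        shuffled["x"] = rng.permutation(shuffled["x"].to_numpy())
        assert accuracy(y, predict_fn(shuffled)) < baseline
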