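"""Isotonic/Platt calibration maps, reliability curves, threshold search."""

import numpy as np
import pytest

from ordcrash import (
    CalibrationMap,
    calibrate_class_probs,
    find_optimal_thresholds,
    fit_isotonic,
    fit_platt,
    reliability_curve,
)
from ordcrash.calibration import THRESHOLD_GRID, expected_calibration_error


class TestFitIsotonic:
    def test_pooled_violators_on_four_points(self):
        # oracle-verified: the middle pair (1, 0) pools to 0.5
        m = fit_isotonic(np.array([0.1, 0.3, 0.4, 0.8]), np.array([0, 1, 0, 1]))
        np.testing.assert_allclose(m.apply(np.array([0.1, 0.3, 0.4, 0.8])), [0, 0.5, 0.5, 1])

    def test_sorted_outcomes_need_no_pooling(self):
        m = fit_isotonic(np.array([0.1, 0.2, 0.7, 0.9]), np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(m.apply(np.array([0.1, 0.2, 0.7, 0.9])), [0, 0, 1, 1])

    def test_degenerate_outcomes_give_constant_map(self, caplog):
        with caplog.at_level("WARNING", logger="ordcrash.calibration"):
            m = fit_isotonic(np.array([0.2, 0.8]), np.array([1, 1]))
        np.testing.assert_allclose(m.apply(np.array([0.0, 0.5, 1.0])), 1.0)
        assert any("identical" in r.message for r in caplog.records)

    def test_map_is_monotone(self, rng):
        scores = rng.random(200)
        outcomes = (rng.random(200) < scores).astype(int)
        m = fit_isotonic(scores, outcomes)
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(m.apply(grid)) >= -1e-12)

    def test_beats_identity_map_in_sample(self, rng):
        scores = rng.random(100)
        outcomes = (rng.random(100) < 0.3).astype(int)
        m = fit_isotonic(scores, outcomes)
        assert np.sum((m.apply(scores) - outcomes) ** 2) <= np.sum((scores - outcomes) ** 2)


def test_platt_map_is_monotone_logistic(rng):
    scores = rng.random(300)
    outcomes = (rng.random(300) < scores).astype(int)
    m = fit_platt(scores, outcomes)
    grid = np.linspace(0, 1, 50)
    vals = m.apply(grid)
    assert np.all(np.diff(vals) >= 0) and np.all((vals >= 0) & (vals <= 1))


class TestCalibrateClassProbs:
    def test_identity_maps_recover_input_after_renormalization(self, rng):
        probs = rng.dirichlet(np.ones(3), size=50)
        maps = [CalibrationMap.identity()] * 3
        out = calibrate_class_probs(probs, maps)
        np.testing.assert_allclose(out, probs, atol=1e-3)

    def test_shrinking_one_column_keeps_rows_on_simplex(self):
        probs = np.array([[0.2, 0.3, 0.5], [0.6, 0.3, 0.1]])
        halve = CalibrationMap(
            boundaries=np.linspace(0, 1, 2001), levels=np.linspace(0, 1, 2000) / 2
        )
        maps = [CalibrationMap.identity(), CalibrationMap.identity(), halve]
        out = calibrate_class_probs(probs, maps)
        np.testing.assert_allclose(out.sum(axis=1), 1.0)
        assert np.all(out[:, 2] < probs[:, 2])

    def test_zero_mass_row_becomes_uniform(self, caplog):
        zero = CalibrationMap(boundaries=np.array([0.0, 1.0]), levels=np.array([0.0]))
        with caplog.at_level("WARNING", logger="ordcrash.calibration"):
            out = calibrate_class_probs(np.array([[0.3, 0.7]]), [zero, zero])
        np.testing.assert_allclose(out, [[0.5, 0.5]])


class TestReliabilityCurve:
    def test_bernoulli_scores_sit_on_diagonal(self, rng):
        scores = rng.random(10_000)
        outcomes = (rng.random(10_000) < scores).astype(int)
        table = reliability_curve(scores, outcomes, n_bins=10)
        assert (table["mean_predicted"] - table["fraction_positive"]).abs().max() < 0.05

    def test_constant_scores_collapse_to_one_bin(self):
        table = reliability_curve(np.full(10, 0.3), np.array([1, 1, 1] + [0] * 7))
        assert len(table) == 1
        np.testing.assert_allclose(table.iloc[0][["mean_predicted", "fraction_positive"]], [0.3, 0.3])

    def test_all_ones_land_in_last_bin(self):
        table = reliability_curve(np.ones(5), np.ones(5))
        assert len(table) == 1
        np.testing.assert_allclose(table.iloc[0][["mean_predicted", "fraction_positive"]], [1.0, 1.0])

    def test_expected_calibration_error_weights_by_occupancy(self):
        probs = np.array([0.05] * 98 + [0.95, 0.95])
        outcomes = np.array([1] * 5 + [0] * 93 + [0, 0])
        # the wildly wrong but nearly empty top bin dominates the unweighted
        # mean (~0.48) yet contributes only 2% of the weighted error
        assert expected_calibration_error(probs, outcomes) < 0.05


class TestFindOptimalThresholds:
    def test_perfect_separation_returns_lowest_achieving_grid_point(self):
        cum = np.array([[0.9], [0.8], [0.2], [0.1]])
        labels = np.array([2, 2, 1, 1])
        np.testing.assert_allclose(find_optimal_thresholds(cum, labels), [0.20])

    def test_never_worse_than_default_threshold(self, rng):
        for _ in range(20):
            cum = np.sort(rng.random((60, 2)))[:, ::-1]
            labels = rng.integers(1, 4, size=60)
            thresholds = find_optimal_thresholds(cum, labels)
            for k in range(2):
                y = labels > (k + 1)
                from ordcrash.calibration import _binary_f1_grid

                f1 = _binary_f1_grid(cum[:, k], y, np.array([thresholds[k], 0.5]))
                assert f1[0] >= f1[1] - 1e-12

    def test_no_positive_examples_falls_back_to_half(self, caplog):
        cum = np.array([[0.9, 0.1], [0.7, 0.2]])
        labels = np.array([2, 2])  # never exceeds the second cut
        with caplog.at_level("WARNING", logger="ordcrash.calibration"):
            thresholds = find_optimal_thresholds(cum, labels)
        assert thresholds[1] == 0.5

    def test_thresholds_lie_on_the_grid(self, rng):
        cum = np.sort(rng.random((40, 3)))[:, ::-1]
        labels = rng.integers(1, 5, size=40)
        thresholds = find_optimal_thresholds(cum, labels)
        assert all(t in THRESHOLD_GRID for t in thresholds)
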