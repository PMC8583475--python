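"""Probability calibration and decision-threshold search.

Tree ensembles and models trained on oversampled data emit biased
probabilities; bias in per-class probabilities propagates into the
cumulative probabilities the ordinal threshold rule consumes.  The default
remedy is per-class isotonic calibration: a piecewise-constant,
non-decreasing map from raw score to calibrated probability, fitted by
pool-adjacent-violators on a held-out calibration fold.  Platt scaling (a
logistic fit of outcome on score) is provided as an alternative for small
calibration sets but is not the default.

After the K one-vs-rest maps are applied the rows are renormalized to sum
to one, reconciling the independently calibrated columns into a simplex.

Threshold moving replaces the default 0.5 decision cutoff: for each cut k
the threshold ``T_k`` maximizing the validation-fold F1 of predicting the
binary event ``y > k`` by ``1{cum_k > T}`` is selected from the grid
{0.01, ..., 0.99}, ties going to the smallest threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class CalibrationMap:
    """Monotone score -> probability map.

    For the isotonic method the map is piecewise constant: ``levels[m]`` is
    assigned to scores in ``[boundaries[m], boundaries[m+1])`` (the last
    interval is closed).  Boundaries span [0, 1] and levels are
    non-decreasing, so the map weakly preserves score order.  For Platt
    scaling the map is the fitted logistic curve and ``boundaries`` /
    ``levels`` give its values on a fixed grid for inspection.
    """

    boundaries: np.ndarray
    levels: np.ndarray
    method: str = "isotonic"
    platt_coef: tuple[float, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.boundaries.shape[0] != self.levels.shape[0] + 1:
            raise ValueError("need one more boundary than levels")
        if np.any(np.diff(self.boundaries) < 0):
            raise ValueError("boundaries must be non-decreasing")
        if self.method == "isotonic" and np.any(np.diff(self.levels) < -1e-12):
            raise ValueError("isotonic levels must be non-decreasing")

    def apply(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.method == "platt":
            a, b = self.platt_coef
            return 1.0 / (1.0 + np.exp(-(a * scores + b)))
        idx = np.searchsorted(self.boundaries, scores, side="right") - 1
        idx = np.clip(idx, 0, self.levels.shape[0] - 1)
        return self.levels[idx]

    @classmethod
    def identity(cls) -> "CalibrationMap":
        """Fine step approximation of the identity map (for testing/plumbing)."""
        edges = np.linspace(0.0, 1.0, 2001)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return cls(boundaries=edges, levels=mids)


def fit_isotonic(scores: np.ndarray, outcomes: np.ndarray) -> CalibrationMap:
    """Fit a non-decreasing step calibration map by isotonic regression.

    Solves the monotone least-squares problem (pool-adjacent-violators):
    outcomes sorted by score are replaced by the best non-decreasing fit,
    and each block of constant fitted value becomes one calibration bin.
    In-sample squared error never exceeds that of the identity map.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have equal length")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 points to calibrate")
    if np.unique(outcomes).shape[0] == 1:
        logger.warning("all outcomes identical; constant calibration map")
        const = float(outcomes[0])
        return CalibrationMap(boundaries=np.array([0.0, 1.0]), levels=np.array([const]))

    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True, out_of_bounds="clip")
    iso.fit(scores, outcomes)

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    fitted = iso.predict(s_sorted)
    # collapse consecutive equal fitted values into constant blocks
    change = np.flatnonzero(np.abs(np.diff(fitted)) > 1e-12) + 1
    starts = np.concatenate([[0], change])
    levels = fitted[starts]
    inner = np.array(
        [0.5 * (s_sorted[i - 1] + s_sorted[i]) for i in change], dtype=float
    )
    boundaries = np.concatenate([[0.0], inner, [1.0]])
    return CalibrationMap(boundaries=boundaries, levels=levels)


def fit_platt(scores: np.ndarray, outcomes: np.ndarray) -> CalibrationMap:
    """Logistic (Platt) calibration: fit ``p = sigmoid(a*score + b)``."""
    from sklearn.linear_model import LogisticRegression

    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if np.unique(outcomes).shape[0] == 1:
        logger.warning("all outcomes identical; constant calibration map")
        const = float(outcomes[0])
        return CalibrationMap(
            boundaries=np.array([0.0, 1.0]), levels=np.array([const]), method="platt",
            platt_coef=(0.0, 50.0 if const == 1.0 else -50.0),
        )
    lr = LogisticRegression(C=1e6, max_iter=1000)
    lr.fit(scores[:, None], outcomes)
    a, b = float(lr.coef_[0, 0]), float(lr.intercept_[0])
    grid = np.linspace(0.0, 1.0, 101)
    mids = 0.5 * (grid[:-1] + grid[1:])
    vals = 1.0 / (1.0 + np.exp(-(a * mids + b)))
    return CalibrationMap(boundaries=grid, levels=vals, method="platt", platt_coef=(a, b))


def calibrate_class_probs(probs: np.ndarray, maps: list[CalibrationMap]) -> np.ndarray:
    """Apply one-vs-rest calibration maps per class column, then renormalize.

    Renormalization reconciles the K independently calibrated columns back
    onto the probability simplex.  A row mapped to all zeros becomes
    uniform (logged).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape[1] != len(maps):
        raise ValueError(f"need {probs.shape[1]} maps, got {len(maps)}")
    out = np.column_stack([m.apply(probs[:, k]) for k, m in enumerate(maps)])
    sums = out.sum(axis=1)
    dead = sums <= 0
    if dead.any():
        logger.warning("%d row(s) calibrated to zero mass; set uniform", int(dead.sum()))
        out[dead] = 1.0 / probs.shape[1]
        sums[dead] = 1.0
    return out / sums[:, None]


def reliability_curve(
    probs_column: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Reliability table: mean predicted probability vs fraction of positives.

    Samples are binned by predicted probability on equal-width bins over
    [0, 1] (last bin closed); empty bins are omitted.  A perfectly
    calibrated predictor puts every row of the table on the diagonal.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(probs_column, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "mean_predicted": p[sel].mean(),
                "fraction_positive": y[sel].mean(),
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["mean_predicted", "fraction_positive", "count"])


def expected_calibration_error(
    probs_column: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> float:
    """Count-weighted mean absolute reliability-bin deviation (ECE).

    Weighting by bin occupancy keeps sparsely populated bins — ubiquitous
    for rare classes, whose predicted probabilities pile up near zero —
    from dominating the summary.
    """
    table = reliability_curve(probs_column, outcomes, n_bins=n_bins)
    weights = table["count"] / table["count"].sum()
    return float((weights * (table["mean_predicted"] - table["fraction_positive"]).abs()).sum())


def _binary_f1_grid(cum_col: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """F1 of ``1{cum_col > T}`` against binary y, for every T in grid."""
    preds = cum_col[:, None] > grid[None, :]
    tp = (preds & y[:, None]).sum(axis=0).astype(float)
    fp = preds.sum(axis=0) - tp
    fn = y.sum() - tp
    denom = 2 * tp + fp + fn
    f1 = np.zeros_like(denom, dtype=float)
    np.divide(2 * tp, denom, out=f1, where=denom > 0)
    return f1


def find_optimal_thresholds(
    cum: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray | None = None,
    joint: bool = False,
) -> np.ndarray:
    """F1-maximizing decision thresholds for the cumulative-threshold rule.

    For each cut k independently, select the grid threshold maximizing the
    binary F1 of predicting ``label > k`` by ``1{cum_k > T}``; ties break to
    the smallest threshold, so the result never has lower validation F1
    than the default 0.5 (which is on the grid).  With ``joint=True`` a
    coordinate-ascent refinement maximizing macro-F1 of the full ordinal
    prediction is run from the per-cut solution.

    A cut with no positive validation examples falls back to 0.5 (logged).
    """
    from ordcrash.methods import proposed_predict

    cum = np.asarray(cum, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if grid is None:
        grid = THRESHOLD_GRID
    n_cuts = cum.shape[1]
    thresholds = np.empty(n_cuts)
    for k in range(n_cuts):
        y = labels > (k + 1)
        if y.sum() == 0:
            logger.warning("no positives for cut %d in validation; T=0.5", k + 1)
            thresholds[k] = 0.5
            continue
        f1 = _binary_f1_grid(cum[:, k], y, grid)
        thresholds[k] = grid[int(np.argmax(f1))]

    if joint:
        from sklearn.metrics import f1_score

        K = n_cuts + 1

        def macro(ts):
            pred = proposed_predict(cum, ts)
            return f1_score(labels, pred, labels=range(1, K + 1), average="macro", zero_division=0)

        best = macro(thresholds)
        improved = True
        while improved:
            improved = False
            for k in range(n_cuts):
                trial = thresholds.copy()
                for t in grid:
                    trial[k] = t
                    s = macro(trial)
                    if s > best + 1e-12:
                        best, thresholds = s, trial.copy()
                        improved = True
    return thresholds
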