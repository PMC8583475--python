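"""Metrics, cross-validation protocols, the 5x2cv paired t-test, and
permutation feature importance.

The evaluation protocol is stratified 10-fold cross-validation with an
8/1/1 rotation: eight folds train the model (with oversampling when
required), one fold serves probability calibration and threshold
optimization, and the last fold tests.  Classifier comparisons use the
5x2 cross-validated paired t-test: five repetitions of 2-fold
cross-validation, with the statistic referred to a Student t distribution
with 5 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class ClassMetricsReport:
    """Per-class precision/recall/F1 plus macro averages and confusion counts."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray
    K: int

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like the published per-class reports (fractions)."""
        rows = {
            "precision": list(self.precision) + [self.macro_precision],
            "recall": list(self.recall) + [self.macro_recall],
            "f1": list(self.f1) + [self.macro_f1],
        }
        index = [f"class_{k}" for k in range(1, self.K + 1)] + ["macro"]
        return pd.DataFrame(rows, index=index)


@dataclass
class ComparisonResult:
    """Outcome of a 5x2cv paired t-test between two methods."""

    deltas: np.ndarray  # 5 x 2 per-fold score differences (a minus b)
    t_statistic: float
    p_value: float
    df: int = 5
    alpha_critical: float = field(default=0.0)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def compute_metrics(true_labels, predicted_labels, K: int) -> ClassMetricsReport:
    """Per-class and macro precision/recall/F1 with a K x K confusion matrix.

    A class never predicted (or never present) gets 0 for the undefined
    ratio, with a logged warning.
    """
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label lengths differ")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if v.size and (v.min() < 1 or v.max() > K):
            raise ValueError(f"{name} labels outside 1..{K}")
    labels = list(range(1, K + 1))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    if np.any(pred_tot == 0) or np.any(true_tot == 0):
        logger.warning("zero denominator in precision/recall; reporting 0")
    precision = np.divide(tp, pred_tot, out=np.zeros(K), where=pred_tot > 0)
    recall = np.divide(tp, true_tot, out=np.zeros(K), where=true_tot > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros(K), where=denom > 0)
    return ClassMetricsReport(precision=precision, recall=recall, f1=f1, confusion=cm, K=K)


def stratified_cv_811(
    labels: np.ndarray, n_folds: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Stratified folds with a train/calibration/test rotation.

    Returns ``n_folds`` triples of index arrays ``(train, calibration,
    test)``: fold j tests, fold (j+1) mod n calibrates, the rest train.
    Every fold is the test fold exactly once and the three parts are
    disjoint by construction.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < n_folds]
    if too_small.size:
        raise ValueError(
            f"class(es) {too_small.tolist()} have fewer than {n_folds} members; "
            "cannot stratify"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros_like(labels), labels)]
    splits = []
    for j in range(n_folds):
        test = folds[j]
        cal = folds[(j + 1) % n_folds]
        train = np.concatenate([folds[m] for m in range(n_folds) if m not in (j, (j + 1) % n_folds)])
        splits.append((np.sort(train), np.sort(cal), np.sort(test)))
    return splits


def critical_value(confidence: float = 0.95, df: int = 5) -> float:
    """Two-sided critical value of the Student t reference distribution."""
    return float(stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, df))


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    labels = np.unique(np.asarray(y_true))
    return float(
        f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)
    )


def five_two_cv_ttest(
    method_a: Callable,
    method_b: Callable,
    X: np.ndarray,
    y: np.ndarray,
    metric: Callable = accuracy,
    seed: int = 0,
    variant: str = "dietterich",
    max_redraws: int = 20,
) -> ComparisonResult:
    """5x2 cross-validated paired t-test between two classification methods.

    Each method is a callable ``method(X_train, y_train, X_test, seed) ->
    predicted labels``.  Five independent 2-fold splits are drawn; per
    repetition i and fold j the score difference is ``delta_ij =
    metric(a) - metric(b)``.

    With ``variant="dietterich"`` (default) the statistic is the standard
    one: ``t = delta_11 / sqrt(mean_i s_i^2)`` where ``s_i^2`` uses the
    per-repetition mean of the two fold differences.  The
    ``variant="first_repetition"`` form instead uses the first repetition's mean both
    as numerator and as the center of every squared deviation.  Both are
    referred two-sided to t with 5 degrees of freedom; identical methods
    give all-zero differences and (t, p) = (0, 1).

    A fold on which the metric raises (e.g. an empty class) causes that
    repetition's split to be re-drawn with the next seed (logged).
    """
    if variant not in ("dietterich", "first_repetition"):
        raise ValueError(f"unknown variant {variant!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    deltas = np.zeros((5, 2))
    draw = 0
    for i in range(5):
        for attempt in range(max_redraws):
            split_seed = seed + 1000 * draw
            draw += 1
            skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=split_seed)
            try:
                pair = []
                for j, (tr, te) in enumerate(skf.split(X, y)):
                    pa = method_a(X[tr], y[tr], X[te], split_seed + j)
                    pb = method_b(X[tr], y[tr], X[te], split_seed + j)
                    pair.append(metric(y[te], pa) - metric(y[te], pb))
                deltas[i] = pair
                break
            except ValueError as exc:
                logger.warning("repetition %d redrawn (%s)", i + 1, exc)
        else:
            raise RuntimeError(f"could not draw a valid split for repetition {i + 1}")

    if variant == "dietterich":
        mu_i = deltas.mean(axis=1)
        s2 = ((deltas - mu_i[:, None]) ** 2).sum(axis=1)
        denom = np.sqrt(s2.mean())
        numer = deltas[0, 0]
    else:
        mu = deltas[0].mean()
        denom = np.sqrt(((deltas - mu) ** 2).sum() / 5.0)
        numer = mu
    if denom == 0:
        t = 0.0 if numer == 0 else np.inf * np.sign(numer)
    else:
        t = float(numer / denom)
    p = 1.0 if t == 0 else float(2.0 * stats.t.sf(abs(t), 5))
    return ComparisonResult(
        deltas=deltas,
        t_statistic=t,
        p_value=p,
        df=5,
        alpha_critical=critical_value(0.95, 5),
    )


def permutation_importance(
    predict_fn: Callable,
    features: pd.DataFrame,
    y: np.ndarray,
    metric: Callable = macro_f1,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance on held-out data.

    Importance of a feature is the drop in the metric after shuffling that
    column, averaged over ``n_repeats`` seeded shuffles.  ``predict_fn``
    maps a feature table to predicted labels.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=int)
    baseline = metric(y, predict_fn(features))
    rows = []
    for col in features.columns:
        drops = []
        for _ in range(n_repeats):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops.append(baseline - metric(y, predict_fn(shuffled)))
        drops = np.asarray(drops)
        rows.append(
            {"feature": col, "importance": drops.mean(), "std": drops.std(ddof=0)}
        )
    return pd.DataFrame(rows).sort_values("importance", ascending=False, ignore_index=True)
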