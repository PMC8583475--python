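"""End-to-end drivers tying combination, sampling, learning, calibration,
thresholding and evaluation together.

Two entry points:

* :func:`evaluate_method` runs the full stratified 10-fold protocol with
  the 8/1/1 train/calibration/test rotation for a named method and
  aggregates per-class metrics across the rotation;
* :func:`make_method_runner` packages a method as a plain
  ``(X_train, y_train, X_test, seed) -> predictions`` callable for the
  5x2cv paired t-test and permutation importance.  Methods that need a
  calibration fold (the cumulative-threshold method and the fitted-weight
  Beckham variant) carve a stratified 20% calibration subset out of their
  training data when no explicit fold is supplied.

Sampling, calibration and threshold search only ever see training or
calibration rows; the driver asserts the three index sets are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from ordcrash.calibration import (
    calibrate_class_probs,
    find_optimal_thresholds,
    fit_isotonic,
    fit_platt,
)
from ordcrash.dataset import CombinationScheme, OrdinalDataset, combine_categories
from ordcrash.decompose import cumulative_decompose, onevsall_decompose
from ordcrash.evaluation import ClassMetricsReport, compute_metrics, stratified_cv_811
from ordcrash.learners import (
    features_matrix,
    fit_multiclass_model,
    fit_onevsall_models,
    make_learner,
    predict_class_scores,
    predict_multiclass_probs,
)
from ordcrash.methods import (
    beckham2_fit,
    beckham_predict,
    cheng_predict,
    class_to_cumulative,
    frank_predict,
    nominal_baseline_predict,
    proposed_predict,
)
from ordcrash.sampling import make_sampling_plan, smote_nc_oversample

logger = logging.getLogger(__name__)

METHODS = ("nominal", "frank", "cheng", "beckham1", "beckham2", "proposed")

_CALIBRATORS = {"isotonic": fit_isotonic, "platt": fit_platt}


def _fit_cumulative_models(X, y, K, learner_spec, seed):
    """K-1 independent binary models for the exceedance targets y > k."""
    targets = cumulative_decompose(y, K).values
    models = []
    for k in range(K - 1):
        col = targets[:, k]
        if col.min() == col.max():
            raise ValueError(f"exceedance target y>{k + 1} is constant in training data")
        model = make_learner(learner_spec, seed=seed + k)
        model.fit(np.asarray(X, dtype=float), col)
        models.append(model)
    return models


def _predict_cumulative(models, X):
    cols = []
    for model in models:
        proba = model.predict_proba(np.asarray(X, dtype=float))
        cols.append(proba[:, -1] if proba.shape[1] == 2 else proba[:, 0])
    return np.clip(np.column_stack(cols), 0.0, 1.0)


@dataclass
class FoldResult:
    """Predictions plus diagnostics from one train/calibrate/test pass."""

    predictions: np.ndarray
    thresholds: np.ndarray | None = None
    beta: np.ndarray | None = None
    calibration_maps: list = field(default_factory=list)


def run_fold(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_cal: np.ndarray | None,
    y_cal: np.ndarray | None,
    X_test: np.ndarray,
    K: int,
    learner_spec=None,
    calibrator: str = "isotonic",
    seed: int = 0,
) -> FoldResult:
    """Fit one method on a train fold and predict the test fold.

    ``X_cal``/``y_cal`` are required for ``proposed`` (calibration maps and
    threshold search) and ``beckham2`` (weight fitting) and ignored by the
    other methods.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")

    if method == "nominal":
        model = fit_multiclass_model(X_train, y_train, K, learner_spec, seed)
        probs = predict_multiclass_probs(model, X_test, K)
        return FoldResult(predictions=nominal_baseline_predict(probs))

    if method in ("frank", "cheng"):
        models = _fit_cumulative_models(X_train, y_train, K, learner_spec, seed)
        cum = _predict_cumulative(models, X_test)
        pred = frank_predict(cum) if method == "frank" else cheng_predict(cum)
        return FoldResult(predictions=pred)

    if method == "beckham1":
        model = fit_multiclass_model(X_train, y_train, K, learner_spec, seed)
        probs = predict_multiclass_probs(model, X_test, K)
        beta = np.arange(1, K + 1, dtype=float)
        return FoldResult(predictions=beckham_predict(probs, beta), beta=beta)

    if method == "beckham2":
        if X_cal is None:
            raise ValueError("beckham2 needs a calibration/validation fold")
        model = fit_multiclass_model(X_train, y_train, K, learner_spec, seed)
        beta = beckham2_fit(predict_multiclass_probs(model, X_cal, K), y_cal)
        probs = predict_multiclass_probs(model, X_test, K)
        return FoldResult(predictions=beckham_predict(probs, beta), beta=beta)

    # proposed: K one-vs-all models -> isotonic maps -> cumulative -> thresholds
    if X_cal is None:
        raise ValueError("proposed needs a calibration/validation fold")
    fit_map = _CALIBRATORS[calibrator]
    model_set = fit_onevsall_models(X_train, y_train, K, learner_spec, seed)
    scores_cal = predict_class_scores(model_set, X_cal)
    onehot_cal = onevsall_decompose(y_cal, K).values
    maps = [fit_map(scores_cal[:, k], onehot_cal[:, k]) for k in range(K)]
    cal_probs = calibrate_class_probs(scores_cal, maps)
    thresholds = find_optimal_thresholds(class_to_cumulative(cal_probs), y_cal)
    test_probs = calibrate_class_probs(predict_class_scores(model_set, X_test), maps)
    pred = proposed_predict(class_to_cumulative(test_probs), thresholds)
    return FoldResult(predictions=pred, thresholds=thresholds, calibration_maps=maps)


@dataclass
class EvaluationResult:
    """Cross-validated evaluation of one method."""

    method: str
    report: ClassMetricsReport  # metrics of pooled test-fold predictions
    fold_reports: list[ClassMetricsReport]
    thresholds: list[np.ndarray]
    K: int

    def mean_frame(self):
        """Per-class metrics averaged over the fold rotation (fractions)."""
        import pandas as pd

        frames = [r.to_frame() for r in self.fold_reports]
        return sum(frames) / len(frames)


def evaluate_method(
    dataset: OrdinalDataset,
    method: str,
    scheme: CombinationScheme | None = None,
    learner_spec=None,
    sampling: bool = True,
    threshold_fraction: float = 0.20,
    target_fraction: float = 0.20,
    k_neighbors: int = 5,
    calibrator: str = "isotonic",
    n_folds: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Full protocol: combine, split, oversample, fit, calibrate, predict.

    Stratified ``n_folds``-fold rotation with 8/1/1 train/calibration/test
    parts (for the default ten folds).  Oversampling, when enabled, uses
    the selection rule (classes under ``threshold_fraction`` of the
    majority, grown to ``target_fraction`` of it) on the training part
    only.  Per-fold metrics are kept individually and for the pooled
    test predictions.
    """
    if scheme is not None:
        dataset = combine_categories(dataset, scheme)
    K = dataset.K
    splits = stratified_cv_811(dataset.labels, n_folds=n_folds, seed=seed)

    fold_reports, thresholds_log = [], []
    pooled_true, pooled_pred = [], []
    for fold_id, (tr, cal, te) in enumerate(splits):
        assert not (set(tr) & set(cal) or set(tr) & set(te) or set(cal) & set(te)), (
            "leakage: overlapping folds"
        )
        train_ds = dataset.subset(tr)
        if sampling:
            plan = make_sampling_plan(
                train_ds.class_counts(),
                threshold_fraction=threshold_fraction,
                target_fraction=target_fraction,
                k_neighbors=k_neighbors,
                seed=seed + fold_id,
            )
            before = train_ds.class_counts()
            train_ds = smote_nc_oversample(train_ds, plan)
            logger.info(
                "fold %d: class counts %s -> %s", fold_id, before, train_ds.class_counts()
            )
        X_train = features_matrix(train_ds)
        X_cal = features_matrix(dataset.subset(cal))
        X_test = features_matrix(dataset.subset(te))
        result = run_fold(
            method,
            X_train,
            train_ds.labels,
            X_cal,
            dataset.labels[cal],
            X_test,
            K,
            learner_spec=learner_spec,
            calibrator=calibrator,
            seed=seed + fold_id,
        )
        if result.thresholds is not None:
            thresholds_log.append(result.thresholds)
            logger.info("fold %d: thresholds %s", fold_id, np.round(result.thresholds, 3))
        fold_reports.append(compute_metrics(dataset.labels[te], result.predictions, K))
        pooled_true.append(dataset.labels[te])
        pooled_pred.append(result.predictions)

    report = compute_metrics(np.concatenate(pooled_true), np.concatenate(pooled_pred), K)
    return EvaluationResult(
        method=method,
        report=report,
        fold_reports=fold_reports,
        thresholds=thresholds_log,
        K=K,
    )


def make_method_runner(
    method: str,
    K: int,
    learner_spec=None,
    sampling: bool = False,
    calibrator: str = "isotonic",
    cal_fraction: float = 0.2,
):
    """Package a method as ``run(X_train, y_train, X_test, seed) -> labels``.

    For use in the 5x2cv paired t-test, where each half of the data is in
    turn the training set.  Methods needing a validation fold split one
    off the training half internally (stratified, ``cal_fraction``).
    """
    needs_cal = method in ("proposed", "beckham2")

    def run(X_train, y_train, X_test, seed=0):
        X_train = np.asarray(X_train, dtype=float)
        y_train = np.asarray(y_train, dtype=int)
        X_cal = y_cal = None
        if needs_cal:
            X_train, X_cal, y_train, y_cal = train_test_split(
                X_train,
                y_train,
                test_size=cal_fraction,
                stratify=y_train,
                random_state=seed % (2**31),
            )
        if sampling:
            import pandas as pd

            counts = {int(c): int(n) for c, n in zip(*np.unique(y_train, return_counts=True))}
            plan = make_sampling_plan(counts, seed=seed % (2**31))
            ds = OrdinalDataset(
                features=pd.DataFrame(X_train),
                labels=y_train,
                categorical_mask=np.zeros(X_train.shape[1], dtype=bool),
                K=K,
            )
            ds = smote_nc_oversample(ds, plan)
            X_train, y_train = ds.features.to_numpy(dtype=float), ds.labels
        result = run_fold(
            method,
            X_train,
            y_train,
            X_cal,
            y_cal,
            np.asarray(X_test, dtype=float),
            K,
            learner_spec=learner_spec,
            calibrator=calibrator,
            seed=seed % (2**31),
        )
        return result.predictions

    return run
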