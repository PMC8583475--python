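"""Pluggable probabilistic base classifiers.

Every ordinal method in this package is a thin layer over one or more
probabilistic classifiers, so any learner exposing the scikit-learn
``fit`` / ``predict_proba`` surface can serve as the base model.  The
factory :func:`make_learner` builds a fresh, seeded estimator from a small
spec (name plus optional hyperparameter overrides).  The default is
gradient-boosted decision trees, which take categorical features as plain
integer codes; an optional one-hot transform is available for learners that
need it.

Fitting the same learner spec with the same seed on the same data yields
identical predictions (determinism contract; the default learner runs
single-threaded).
"""

from __future__ import annotations

import copy
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ordcrash.dataset import OrdinalDataset
from ordcrash.decompose import onevsall_decompose

logger = logging.getLogger(__name__)

#: Fixed defaults for the gradient-boosted tree learner.  No hyperparameter
#: search is performed; these are sensible mid-range settings.
XGB_DEFAULTS: dict = {
    "n_estimators": 300,
    "max_depth": 6,
    "learning_rate": 0.1,
    "subsample": 0.8,
    "tree_method": "hist",
    "n_jobs": 1,
    "verbosity": 0,
}

#: Lighter tree preset for repeated benchmark runs.
XGB_FAST: dict = {**XGB_DEFAULTS, "n_estimators": 200, "max_depth": 4}


def make_learner(spec: str | Mapping | None = None, seed: int = 0):
    """Build a fresh probabilistic classifier from a spec.

    Parameters
    ----------
    spec : str or mapping, optional
        Either a learner name (``"xgboost"``, ``"xgboost_fast"``,
        ``"logistic"``, ``"mlp"``, ``"svm"``) or a mapping with a ``name``
        key plus hyperparameter overrides.  Default: ``"xgboost"``.
    seed : int
        Random seed passed to the estimator.
    """
    if spec is None:
        spec = "xgboost"
    if isinstance(spec, str):
        name, params = spec, {}
    else:
        spec = dict(spec)
        name = spec.pop("name", "xgboost")
        params = spec

    if name in ("xgboost", "xgboost_fast"):
        from xgboost import XGBClassifier

        base = copy.deepcopy(XGB_FAST if name == "xgboost_fast" else XGB_DEFAULTS)
        base.update(params)
        return XGBClassifier(random_state=seed, **base)
    if name == "logistic":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if name == "mlp":
        from sklearn.neural_network import MLPClassifier

        defaults = {"hidden_layer_sizes": (64, 10), "activation": "relu", "max_iter": 300}
        defaults.update(params)
        return MLPClassifier(random_state=seed, **defaults)
    if name == "svm":
        from sklearn.svm import SVC

        defaults = {"kernel": "rbf", "probability": True}
        defaults.update(params)
        return SVC(random_state=seed, **defaults)
    raise ValueError(f"unknown learner {name!r}")


def features_matrix(dataset: OrdinalDataset, one_hot: bool = False) -> np.ndarray:
    """Numeric design matrix for a learner.

    Categorical columns become integer codes (tree learners consume these
    directly); with ``one_hot=True`` they are expanded to indicator columns
    for learners sensitive to arbitrary numeric encodings.
    """
    cols = []
    for j, name in enumerate(dataset.features.columns):
        col = dataset.features[name]
        if dataset.categorical_mask[j]:
            codes = col if pd.api.types.is_numeric_dtype(col) else col.astype("category").cat.codes
            if one_hot:
                dummies = pd.get_dummies(codes, prefix=str(name))
                cols.append(dummies.to_numpy(dtype=float))
                continue
            cols.append(np.asarray(codes, dtype=float)[:, None])
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(cols)


class OneVsAllModelSet:
    """K single-output binary models, one per one-vs-all target column."""

    def __init__(self, models: Sequence, K: int, n_features: int):
        self.models = list(models)
        self.K = K
        self.n_features = n_features


def fit_onevsall_models(
    X: np.ndarray, labels: np.ndarray, K: int, learner_spec=None, seed: int = 0
) -> OneVsAllModelSet:
    """Fit K binary classifiers on the one-vs-all decomposition of labels.

    Raises if some class has no training rows: its binary model would see a
    single outcome value and cannot be fit meaningfully.
    """
    X = np.asarray(X, dtype=float)
    targets = onevsall_decompose(labels, K).values
    for k in range(K):
        if targets[:, k].sum() == 0:
            raise ValueError(f"class {k + 1} absent from training data")
    models = []
    for k in range(K):
        model = make_learner(learner_spec, seed=seed + k)
        model.fit(X, targets[:, k])
        models.append(model)
    return OneVsAllModelSet(models, K=K, n_features=X.shape[1])


def predict_class_scores(model_set: OneVsAllModelSet, X: np.ndarray) -> np.ndarray:
    """Stack per-class positive scores into an N x K matrix, clipped to [0, 1].

    Rows are NOT renormalized here: the K binary models are independent, so
    their scores need not sum to one.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model_set.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} != training feature count "
            f"{model_set.n_features}"
        )
    cols = []
    for model in model_set.models:
        proba = model.predict_proba(X)
        # positive-class column; a degenerate single-class fit yields one column
        pos = proba[:, -1] if proba.shape[1] == 2 else proba[:, 0]
        cols.append(pos)
    scores = np.column_stack(cols)
    if scores.min() < 0 or scores.max() > 1:
        logger.warning("raw learner scores outside [0, 1]; clipping")
        scores = np.clip(scores, 0.0, 1.0)
    return scores


def fit_multiclass_model(
    X: np.ndarray, labels: np.ndarray, K: int, learner_spec=None, seed: int = 0
):
    """Fit one multiclass model; wraps the 1..K <-> 0..K-1 label shift."""
    X = np.asarray(X, dtype=float)
    present = np.unique(labels)
    missing = set(range(1, K + 1)) - set(present.tolist())
    if missing:
        raise ValueError(f"class(es) {sorted(missing)} absent from training data")
    model = make_learner(learner_spec, seed=seed)
    model.fit(X, np.asarray(labels, dtype=int) - 1)
    return model


def predict_multiclass_probs(model, X: np.ndarray, K: int) -> np.ndarray:
    """N x K class-probability matrix from a multiclass model (rows sum to 1)."""
    proba = model.predict_proba(np.asarray(X, dtype=float))
    if proba.shape[1] != K:
        raise ValueError(f"model emits {proba.shape[1]} classes, expected {K}")
    return proba
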