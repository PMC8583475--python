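"""SMOTE-NC oversampling and the minority-class selection rule.

Classes whose instance count falls below 20% of the majority class are
oversampled until they reach exactly one-fifth of the majority size (both
fractions configurable).  Synthetic rows are produced by SMOTE-NC, which
handles mixed feature types: continuous coordinates are interpolated
uniformly between a minority instance and one of its k nearest minority
neighbors, while each categorical value is the most frequent category among
those k neighbors.  Distances are Euclidean on continuous features
standardized by training-fold statistics, plus a penalty per categorical
mismatch equal to the median of the standardized continuous features'
standard deviations within the minority class.

Oversampling is append-only (original rows are never altered) and is meant
to run inside cross-validation on training folds only, never on calibration
or test folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ordcrash.dataset import OrdinalDataset

logger = logging.getLogger(__name__)


@dataclass
class SamplingPlan:
    """Which classes to oversample and to what target counts."""

    classes_to_oversample: set[int] = field(default_factory=set)
    target_counts: dict[int, int] = field(default_factory=dict)
    k_neighbors: int = 5
    seed: int = 0


def make_sampling_plan(
    class_counts: dict[int, int],
    threshold_fraction: float = 0.20,
    target_fraction: float = 0.20,
    k_neighbors: int = 5,
    seed: int = 0,
) -> SamplingPlan:
    """Select minority classes and target sizes.

    A class is selected iff its count is strictly below
    ``threshold_fraction`` times the majority count; its target is
    ``round(target_fraction * majority_count)`` (never below its current
    count).  A tie for the majority class is an error: the rule is
    ambiguous without a unique majority.
    """
    counts = {int(c): int(n) for c, n in class_counts.items() if n > 0}
    if not counts:
        raise ValueError("no non-empty classes")
    majority_size = max(counts.values())
    majority = [c for c, n in counts.items() if n == majority_size]
    if len(majority) > 1:
        raise ValueError(f"tie for majority class among {sorted(majority)}")
    selected = {
        c for c, n in counts.items() if n < threshold_fraction * majority_size
    }
    targets = {
        c: max(counts[c], int(round(target_fraction * majority_size)))
        for c in selected
    }
    return SamplingPlan(
        classes_to_oversample=selected,
        target_counts=targets,
        k_neighbors=k_neighbors,
        seed=seed,
    )


def _mismatch_penalty(cont_std: np.ndarray) -> float:
    """Categorical-mismatch distance: median of minority-class std devs."""
    if cont_std.size == 0:
        return 1.0
    med = float(np.median(cont_std))
    return med if med > 0 else 1.0


def smote_nc_oversample(dataset: OrdinalDataset, plan: SamplingPlan) -> OrdinalDataset:
    """Grow each planned class to its target count with SMOTE-NC rows.

    Synthetic rows are appended after the original rows; the class counts
    of the result match the plan targets exactly.  Fully reproducible from
    ``plan.seed``.
    """
    rng = np.random.default_rng(plan.seed)
    cont_cols = [c for c, is_cat in zip(dataset.features.columns, dataset.categorical_mask) if not is_cat]
    cat_cols = [c for c, is_cat in zip(dataset.features.columns, dataset.categorical_mask) if is_cat]

    # standardization statistics from the full training fold
    if cont_cols:
        cont_all = dataset.features[cont_cols].to_numpy(dtype=float)
        mu = cont_all.mean(axis=0)
        sd = cont_all.std(axis=0)
        sd[sd == 0] = 1.0

    new_frames: list[pd.DataFrame] = []
    new_labels: list[np.ndarray] = []
    for cls in sorted(plan.classes_to_oversample):
        idx = np.flatnonzero(dataset.labels == cls)
        n_min = idx.size
        if n_min < 2:
            raise ValueError(f"class {cls} has {n_min} instance(s); cannot interpolate")
        n_new = plan.target_counts[cls] - n_min
        if n_new <= 0:
            continue
        k = plan.k_neighbors
        if k >= n_min:
            k = n_min - 1
            logger.warning("class %d: k reduced to %d (class size %d)", cls, k, n_min)

        sub = dataset.features.iloc[idx]
        if cont_cols:
            from scipy.spatial.distance import cdist

            Z = (sub[cont_cols].to_numpy(dtype=float) - mu) / sd
            penalty = _mismatch_penalty(Z.std(axis=0))
            d2 = cdist(Z, Z, "sqeuclidean")
        else:
            penalty = 1.0
            d2 = np.zeros((n_min, n_min))
        if cat_cols:
            C = sub[cat_cols].to_numpy()
            mismatch = (C[:, None, :] != C[None, :, :]).sum(axis=2)
            d2 = d2 + (penalty**2) * mismatch
        np.fill_diagonal(d2, np.inf)
        neighbors = np.argsort(d2, axis=1, kind="stable")[:, :k]

        parents = rng.integers(0, n_min, size=n_new)
        chosen = neighbors[parents, rng.integers(0, k, size=n_new)]
        gaps = rng.random(n_new)

        synth = {}
        if cont_cols:
            X = sub[cont_cols].to_numpy(dtype=float)
            interp = X[parents] + gaps[:, None] * (X[chosen] - X[parents])
            for j, c in enumerate(cont_cols):
                synth[c] = interp[:, j]
        for j, c in enumerate(cat_cols):
            vals = sub[c].to_numpy()
            neigh_vals = vals[neighbors[parents]]  # n_new x k
            out = np.empty(n_new, dtype=vals.dtype)
            for i in range(n_new):
                uniq, cnt = np.unique(neigh_vals[i], return_counts=True)
                # majority category; ties -> lowest code
                out[i] = uniq[np.argmax(cnt)]
            synth[c] = out
        frame = pd.DataFrame(synth).reindex(columns=dataset.features.columns)
        new_frames.append(frame)
        new_labels.append(np.full(n_new, cls, dtype=int))
        logger.info("class %d: %d -> %d rows via SMOTE-NC", cls, n_min, plan.target_counts[cls])

    if not new_frames:
        return dataset
    features = pd.concat([dataset.features, *new_frames], ignore_index=True)
    labels = np.concatenate([dataset.labels, *new_labels])
    return OrdinalDataset(
        features=features,
        labels=labels,
        categorical_mask=dataset.categorical_mask,
        K=dataset.K,
        level_names=dataset.level_names,
    )
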