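"""Dataset container, ordinal label encoding, and ordered category combination.

The central container is :class:`OrdinalDataset`: a mixed-type feature table
(categorical columns flagged by a boolean mask) together with an integer
label vector taking values ``1..K`` for ``K`` ordered classes.  Class 1 is
always the least severe level and class K the most severe; the order is
declared by the caller, never inferred from a lexical sort.

Category combination merges the K ordered levels into a smaller number of
ordered classes using contiguous cut points: a scheme with cuts ``(c1, c2)``
maps original level L to class 1 if ``L <= c1``, class 2 if ``c1 < L <= c2``
and class 3 otherwise.  For five severity levels and three classes there are
exactly C(4, 2) = 6 such schemes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OrdinalDataset:
    """Feature table plus ordinal labels in ``{1..K}``.

    Parameters
    ----------
    features : pandas.DataFrame
        N x P table; categorical columns hold integer (or string) codes.
    labels : numpy.ndarray
        Length-N integer vector with values in ``1..K``.
    categorical_mask : numpy.ndarray
        Length-P boolean vector, ``True`` for categorical columns.
    K : int
        Number of ordered classes, at least 2.
    level_names : list of str
        Display names for the K levels, least to most severe.
    """

    features: pd.DataFrame
    labels: np.ndarray
    categorical_mask: np.ndarray
    K: int
    level_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.categorical_mask = np.asarray(self.categorical_mask, dtype=bool)
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.categorical_mask.shape[0] != self.features.shape[1]:
            raise ValueError(
                "categorical_mask length "
                f"{self.categorical_mask.shape[0]} != number of feature "
                f"columns {self.features.shape[1]}"
            )
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels and features row counts differ")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.K):
            bad = self.labels[(self.labels < 1) | (self.labels > self.K)]
            raise ValueError(f"labels outside 1..{self.K}: {np.unique(bad)}")
        if not self.level_names:
            self.level_names = [f"C{k}" for k in range(1, self.K + 1)]
        if len(self.level_names) != self.K:
            raise ValueError("level_names length must equal K")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        """Counts per class id 1..K (absent classes reported as 0)."""
        return {k: int((self.labels == k).sum()) for k in range(1, self.K + 1)}

    def subset(self, idx: np.ndarray) -> "OrdinalDataset":
        """Row subset by positional index; feature table copied."""
        return replace(
            self,
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
        )


@dataclass(frozen=True)
class CombinationScheme:
    """Contiguous ordered partition of K levels into ``len(cuts)+1`` classes.

    ``cuts`` are 1-based upper boundaries: level L maps to the number of
    cuts strictly below L, plus one.
    """

    cuts: tuple[int, ...]
    K: int = 5
    id: int | None = None

    def __post_init__(self) -> None:
        cuts = tuple(self.cuts)
        if not cuts or list(cuts) != sorted(set(cuts)):
            raise ValueError(f"cuts must be strictly increasing, got {cuts}")
        if cuts[0] < 1 or cuts[-1] > self.K - 1:
            raise ValueError(f"cuts {cuts} not within 1..{self.K - 1}")
        object.__setattr__(self, "cuts", cuts)

    @property
    def n_classes(self) -> int:
        return len(self.cuts) + 1

    def apply(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        return np.searchsorted(np.asarray(self.cuts), labels, side="left") + 1


#: Best-effort alias table mapping published combination ids to cut pairs for
#: the 5-level -> 3-class case.  Ids 2 and 3 are pinned by the in-text
#: descriptions (class 2 = {COP, OVI} / class 3 = {SI, KSI} for id 2;
#: class 3 = {OVI, SI, KSI} for id 3); the remaining ids are approximate and
#: can be overridden by passing an explicit cut pair anywhere a scheme is
#: accepted.
PUBLISHED_COMBINATION_ALIASES: dict[int, tuple[int, int]] = {
    1: (1, 4),
    2: (1, 3),
    3: (1, 2),
    4: (2, 4),
    5: (2, 3),
    6: (3, 4),
}


def load_dataset(
    path,
    label_column: str,
    levels: Sequence,
    categorical_columns: Sequence[str] = (),
    feature_columns: Sequence[str] | None = None,
) -> OrdinalDataset:
    """Read a CSV into an :class:`OrdinalDataset`.

    Rows containing any missing value are dropped (listwise deletion) and the
    count is logged.  ``levels`` declares the ordered label values, least to
    most severe; a label value outside it is an error.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row.
    label_column : str
        Name of the ordinal outcome column.
    levels : sequence
        Ordered label values; position i (0-based) encodes to class i+1.
    categorical_columns : sequence of str
        Names of the categorical feature columns.
    feature_columns : sequence of str, optional
        Subset of columns to use as features; defaults to every column
        except the label.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty dataset: {path!r}")
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not in file")

    n_before = len(frame)
    frame = frame.dropna(axis=0, how="any").reset_index(drop=True)
    dropped = n_before - len(frame)
    if dropped:
        logger.info("dropped %d row(s) with missing values", dropped)
    if frame.empty:
        raise ValueError("no rows remain after dropping missing values")

    level_to_code = {lev: i + 1 for i, lev in enumerate(levels)}
    raw = frame[label_column]
    unknown = set(raw.unique()) - set(level_to_code)
    if unknown:
        raise ValueError(
            f"label value(s) {sorted(map(str, unknown))} not in declared "
            f"level order {list(levels)}"
        )
    labels = raw.map(level_to_code).to_numpy(dtype=int)

    if feature_columns is None:
        feature_columns = [c for c in frame.columns if c != label_column]
    missing = set(categorical_columns) - set(feature_columns)
    if missing:
        raise ValueError(f"categorical column(s) {sorted(missing)} not among features")
    features = frame[list(feature_columns)].copy()
    mask = np.array([c in set(categorical_columns) for c in feature_columns])
    return OrdinalDataset(
        features=features,
        labels=labels,
        categorical_mask=mask,
        K=len(levels),
        level_names=[str(v) for v in levels],
    )


def enumerate_schemes(K: int = 5, G: int = 3) -> list[CombinationScheme]:
    """All contiguous ordered partitions of K levels into G non-empty classes.

    Each scheme is a (G-1)-tuple of cut points; there are C(K-1, G-1) of
    them.  Schemes are returned in lexicographic cut order with ids 1..n.
    """
    if not 2 <= G <= K:
        raise ValueError(f"need 2 <= G <= K, got G={G}, K={K}")
    schemes = []
    for i, cuts in enumerate(itertools.combinations(range(1, K), G - 1), start=1):
        schemes.append(CombinationScheme(cuts=cuts, K=K, id=i))
    return schemes


def combine_categories(dataset: OrdinalDataset, scheme: CombinationScheme) -> OrdinalDataset:
    """Merge the dataset's K levels into the scheme's classes.

    The feature table is untouched; only labels, K and level names change.
    The mapping is monotone non-decreasing in the original level.
    """
    if scheme.K != dataset.K:
        raise ValueError(f"scheme is for K={scheme.K}, dataset has K={dataset.K}")
    new_labels = scheme.apply(dataset.labels)
    bounds = (0,) + scheme.cuts + (dataset.K,)
    names = [
        "+".join(dataset.level_names[bounds[g] : bounds[g + 1]])
        for g in range(scheme.n_classes)
    ]
    return OrdinalDataset(
        features=dataset.features,
        labels=new_labels,
        categorical_mask=dataset.categorical_mask,
        K=scheme.n_classes,
        level_names=names,
    )
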