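"""Binary decompositions of an ordinal label.

Two encodings of a label ``y in {1..K}``:

* cumulative: K-1 indicators ``y > k`` for k = 1..K-1, so each row is a run
  of ones followed by zeros;
* one-vs-all: K indicators ``y == k``, so each row is one-hot.

The two are linked by partial summation: cumulative column k equals the sum
of one-vs-all columns k+1..K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BinaryTargetMatrix:
    """N x M binary target matrix produced by a decomposition."""

    values: np.ndarray
    scheme: str  # "cumulative" | "one_vs_all"
    K: int

    def __post_init__(self) -> None:
        if self.scheme not in ("cumulative", "one_vs_all"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        expected = self.K - 1 if self.scheme == "cumulative" else self.K
        if self.values.shape[1] != expected:
            raise ValueError(
                f"{self.scheme} decomposition needs {expected} columns, "
                f"got {self.values.shape[1]}"
            )


def _check_labels(labels: np.ndarray, K: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 1 or labels.max() > K):
        bad = np.unique(labels[(labels < 1) | (labels > K)])
        raise ValueError(f"labels outside 1..{K}: {bad}")
    return labels


def cumulative_decompose(labels: np.ndarray, K: int) -> BinaryTargetMatrix:
    """Encode labels as K-1 exceedance indicators ``1{y > k}``."""
    labels = _check_labels(labels, K)
    ks = np.arange(1, K)
    values = (labels[:, None] > ks[None, :]).astype(int)
    return BinaryTargetMatrix(values=values, scheme="cumulative", K=K)


def onevsall_decompose(labels: np.ndarray, K: int) -> BinaryTargetMatrix:
    """Encode labels as K one-hot indicators ``1{y == k}``."""
    labels = _check_labels(labels, K)
    ks = np.arange(1, K + 1)
    values = (labels[:, None] == ks[None, :]).astype(int)
    return BinaryTargetMatrix(values=values, scheme="one_vs_all", K=K)


def decode_cumulative(values: np.ndarray) -> np.ndarray:
    """Recover labels from a cumulative target matrix (count of ones + 1)."""
    return np.asarray(values).sum(axis=1).astype(int) + 1


def decode_onevsall(values: np.ndarray) -> np.ndarray:
    """Recover labels from a one-hot target matrix (argmax + 1)."""
    return np.asarray(values).argmax(axis=1).astype(int) + 1
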