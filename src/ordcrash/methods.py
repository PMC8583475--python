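"""Ordinal prediction rules: Frank, Cheng, Beckham, and the rank-monotone
cumulative-threshold method, plus the nominal argmax baseline.

All functions operate on plain numpy arrays:

* class-probability matrices are N x K with rows on (or renormalized to)
  the probability simplex;
* cumulative (exceedance) probability matrices are N x (K-1), column k
  holding ``p(y > k)``.

Frank's rule differences cumulative probabilities into class probabilities
and takes the argmax; when the cumulative columns come from independently
trained models the differences can be negative — they are deliberately kept
raw, preserving the benchmark's documented rank-monotonicity weakness.
Cheng's rule counts cumulative probabilities above 0.5.  Beckham's rule
takes a weighted expectation of the class index, with weights either fixed
at 1..K or fitted by least squares.  The cumulative-threshold ("proposed")
rule derives cumulative probabilities from one-vs-all class probabilities
by partial summation — which makes them non-increasing in k by construction
— and counts exceedances of per-cut thresholds.

Tie-breaking everywhere is toward the lower (less severe) class.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def _as_matrix(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {x.shape}")
    return x


def frank_class_probs(cum: np.ndarray) -> np.ndarray:
    """Class probabilities by differencing cumulative probabilities.

    Column 1 is ``1 - cum_1``, column k is ``cum_{k-1} - cum_k`` for the
    middle classes and column K is ``cum_{K-1}``.  Rows telescope to 1.
    Negative entries from non-monotone input are kept, not clipped.
    """
    cum = _as_matrix(cum, "cum")
    return np.hstack([1.0 - cum[:, :1], cum[:, :-1] - cum[:, 1:], cum[:, -1:]])


def frank_predict(cum: np.ndarray) -> np.ndarray:
    """Argmax over Frank class probabilities; ties go to the lowest class."""
    return frank_class_probs(cum).argmax(axis=1) + 1


def cheng_predict(cum: np.ndarray) -> np.ndarray:
    """Count cumulative probabilities strictly above 0.5, plus one.

    Applied literally even when the input violates rank monotonicity.
    """
    cum = _as_matrix(cum, "cum")
    return (cum > 0.5).sum(axis=1) + 1


def beckham_predict(probs: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Weighted-expectation rule: round ``sum_k beta_k p_k`` to a class.

    The continuous score is rounded to the nearest integer with half-way
    ties rounding down, then clipped to [1, K].
    """
    probs = _as_matrix(probs, "probs")
    beta = np.asarray(beta, dtype=float)
    score = probs @ beta
    labels = np.ceil(score - 0.5).astype(int)  # round half down
    return np.clip(labels, 1, probs.shape[1])


def beckham2_fit(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Least-squares class weights: minimize ``sum_i (y_i - probs_i . beta)^2``.

    With one-hot probability rows and correct labels the solution is exactly
    ``beta = (1, ..., K)``.  A rank-deficient design (e.g. all rows uniform)
    yields the minimum-norm solution, with a logged warning.
    """
    probs = _as_matrix(probs, "probs")
    labels = np.asarray(labels, dtype=float)
    if probs.shape[0] < probs.shape[1]:
        raise ValueError("need at least K rows to fit K weights")
    beta, _, rank, _ = np.linalg.lstsq(probs, labels, rcond=None)
    if rank < probs.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d); minimum-norm weights",
            rank,
            probs.shape[1],
        )
    return beta


def class_to_cumulative(probs: np.ndarray) -> np.ndarray:
    """Cumulative exceedance probabilities by partial summation.

    ``cum_k = sum_{j>k} p_j`` after renormalizing each row to sum to one.
    Rows of the result are non-increasing in k and lie in [0, 1] — the
    rank-monotonicity guarantee of the cumulative-threshold method.
    """
    probs = _as_matrix(probs, "probs")
    sums = probs.sum(axis=1)
    if np.any(~np.isfinite(sums)) or np.any(sums < 1e-3):
        raise ValueError("probability rows must be finite with positive mass")
    probs = probs / sums[:, None]
    cum = np.cumsum(probs[:, ::-1], axis=1)[:, ::-1]
    # cum[:, 0] == 1 (total mass); exceedance of cut k is the tail from k+1
    return np.clip(cum[:, 1:], 0.0, 1.0)


def proposed_predict(cum: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Count exceedance probabilities strictly above their thresholds, plus 1.

    With all thresholds at 0.5 this coincides with Cheng's rule on
    rank-monotone input.
    """
    cum = _as_matrix(cum, "cum")
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape[0] != cum.shape[1]:
        raise ValueError(
            f"need {cum.shape[1]} thresholds, got {thresholds.shape[0]}"
        )
    return (cum > thresholds[None, :]).sum(axis=1) + 1


def nominal_baseline_predict(probs: np.ndarray) -> np.ndarray:
    """Plain multiclass argmax; ties go to the lowest class."""
    return _as_matrix(probs, "probs").argmax(axis=1) + 1
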