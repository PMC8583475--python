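"""Seeded generator of crash-severity-like ordinal datasets.

Real crash-severity data is request-only, so every component of this
package is exercised on synthetic data emulating its shape: a mix of
categorical and continuous predictors, five ordered outcome levels with
severe imbalance (majority share about 57%, rarest about 0.5%), and a
monotone latent relationship between features and severity.

The generative model is a latent-threshold (ordered-logit style) design:
a latent score is a weighted sum of the features (categorical levels enter
through monotone per-level offsets) plus logistic noise, and labels are
obtained by thresholding the score at cut points chosen by quantile
matching so the empirical class proportions reproduce the configured ones.
This guarantees the ordinal structure the classification methods assume.
The generator emulates the statistical shape of crash data — imbalance,
mixed types, ordered outcome — not the semantics of any real roadway
variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ordcrash.dataset import OrdinalDataset

#: Empirical severity-level shares the default proportions emulate
#: (non-injury through fatal).
DEFAULT_PROPORTIONS = (0.5720, 0.2960, 0.1080, 0.0193, 0.0047)

#: Crash-data-like shape: 14 categorical predictors of varying cardinality
#: plus 3 continuous ones (ages, model year).
DEFAULT_CARDINALITIES = (2, 2, 2, 2, 3, 3, 4, 4, 5, 6, 6, 8, 9, 12)

SEVERITY_LEVEL_NAMES = ["NIC", "COP", "OVI", "SI", "KSI"]


def _default_weights(n_continuous: int, n_categorical: int) -> np.ndarray:
    """Decaying effect sizes with a clearly dominant first continuous feature."""
    cont = 1.5 * (0.6 ** np.arange(n_continuous))
    cat = 0.9 * (0.8 ** np.arange(n_categorical))
    return np.concatenate([cont, cat])


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic ordinal-data generator.

    ``effect_weights`` covers continuous features first, then categorical
    ones; a categorical feature with weight w and cardinality c contributes
    offsets ``w * linspace(-1, 1, c)`` indexed by its code, so higher codes
    push monotonically toward higher severity.  ``noise_scale`` is the
    scale of the additive logistic noise (1.0 gives an ordered-logit
    latent model).
    """

    N: int = 20_000
    n_continuous: int = 3
    n_categorical: int = 14
    category_cardinalities: tuple[int, ...] = DEFAULT_CARDINALITIES
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    effect_weights: np.ndarray | None = None
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-6:
            raise ValueError(f"class proportions sum to {props.sum():.6f}, not 1")
        if (props <= 0).any():
            raise ValueError("class proportions must be positive")
        if len(self.category_cardinalities) != self.n_categorical:
            raise ValueError("need one cardinality per categorical feature")
        if any(c < 2 for c in self.category_cardinalities):
            raise ValueError("categorical cardinalities must be >= 2")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        K = props.shape[0]
        if self.N < 10 * K:
            raise ValueError(f"N={self.N} too small for K={K} (need >= {10 * K})")
        if self.effect_weights is None:
            self.effect_weights = _default_weights(self.n_continuous, self.n_categorical)
        self.effect_weights = np.asarray(self.effect_weights, dtype=float)
        if self.effect_weights.shape[0] != self.n_continuous + self.n_categorical:
            raise ValueError("effect_weights length must equal total feature count")

    @property
    def K(self) -> int:
        return len(self.class_proportions)


def _latent_pieces(config: GeneratorConfig, rng: np.random.Generator):
    """Draw features and the noiseless latent score."""
    cont = rng.standard_normal((config.N, config.n_continuous))
    cats = np.column_stack(
        [rng.integers(0, c, size=config.N) for c in config.category_cardinalities]
    )
    w = config.effect_weights
    eta = cont @ w[: config.n_continuous]
    for j, c in enumerate(config.category_cardinalities):
        offsets = w[config.n_continuous + j] * np.linspace(-1.0, 1.0, c)
        eta = eta + offsets[cats[:, j]]
    return cont, cats, eta


def _to_dataset(config: GeneratorConfig, cont, cats, labels) -> OrdinalDataset:
    data = {f"cont_{j + 1}": cont[:, j] for j in range(config.n_continuous)}
    data.update({f"cat_{j + 1}": cats[:, j] for j in range(config.n_categorical)})
    features = pd.DataFrame(data)
    mask = np.array([False] * config.n_continuous + [True] * config.n_categorical)
    names = SEVERITY_LEVEL_NAMES if config.K == 5 else [f"C{k}" for k in range(1, config.K + 1)]
    return OrdinalDataset(
        features=features,
        labels=labels,
        categorical_mask=mask,
        K=config.K,
        level_names=list(names),
    )


def generate(config: GeneratorConfig) -> OrdinalDataset:
    """Generate one seeded dataset under the latent-threshold model.

    Cut points are the empirical quantiles of the latent score at the
    configured cumulative proportions, so class shares match the
    configuration up to integer rounding.  The same seed yields an
    identical dataset.
    """
    props = np.asarray(config.class_proportions)
    expected = config.N * props
    if (expected < 2).any():
        worst = int(np.argmin(expected)) + 1
        raise ValueError(
            f"class {worst} expects {expected.min():.2f} rows at N={config.N}; "
            "increase N or adjust proportions"
        )
    rng = np.random.default_rng(config.seed)
    cont, cats, eta = _latent_pieces(config, rng)
    score = eta + rng.logistic(0.0, config.noise_scale, size=config.N)
    cuts = np.quantile(score, np.cumsum(props)[:-1])
    labels = np.digitize(score, cuts) + 1
    return _to_dataset(config, cont, cats, labels)


def generate_calibration_stress(
    config: GeneratorConfig, distortion=None
) -> tuple[OrdinalDataset, np.ndarray, np.ndarray]:
    """Dataset with known true class probabilities and a distorted copy.

    Under the latent-threshold model the true exceedance probabilities are
    logistic in the latent score, class probabilities follow by
    differencing, and labels are drawn from them — so any reliability curve
    computed on the true probabilities sits on the diagonal up to sampling
    noise.  ``distortion`` (a strictly monotone map on [0, 1], default
    identity) is applied elementwise to the class probabilities, which are
    then renormalized: the result is a probability matrix with a known,
    controllable calibration error against the same labels, used to score
    how much of it isotonic calibration removes.

    Returns ``(dataset, true_probs, distorted_probs)``.
    """
    props = np.asarray(config.class_proportions)
    rng = np.random.default_rng(config.seed)
    cont, cats, eta = _latent_pieces(config, rng)
    noise_sample = rng.logistic(0.0, config.noise_scale, size=config.N)
    cuts = np.quantile(eta + noise_sample, np.cumsum(props)[:-1])

    # P(y <= k | x) = sigmoid((cut_k - eta) / s); class probs by differences
    z = (cuts[None, :] - eta[:, None]) / config.noise_scale
    cdf = 1.0 / (1.0 + np.exp(-z))
    cdf = np.hstack([np.zeros((config.N, 1)), cdf, np.ones((config.N, 1))])
    true_probs = np.diff(cdf, axis=1)

    u = rng.random(config.N)
    labels = (u[:, None] >= np.cumsum(true_probs, axis=1)).sum(axis=1) + 1
    labels = np.clip(labels, 1, config.K)

    if distortion is None:
        distorted = true_probs.copy()
    else:
        distorted = np.vectorize(distortion)(true_probs).astype(float)
        if np.any(distorted < 0):
            raise ValueError("distortion must map [0, 1] into [0, inf)")
        distorted = distorted / distorted.sum(axis=1, keepdims=True)

    dataset = _to_dataset(config, cont, cats, labels)
    return dataset, true_probs, distorted
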