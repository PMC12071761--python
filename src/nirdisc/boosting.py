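"""Ordered target statistics and a boosted decision-tree classifier.

Two pieces:

* :func:`ordered_target_statistic` — the leakage-free categorical encoder
  used by ordered boosting.  Samples are visited in a random permutation
  and each categorical value is replaced by the smoothed mean target of
  the *preceding* samples sharing that value:

      x_hat_k = (sum_{j<k, x_j = x_k} y_j + a * p) / (#{j<k, x_j = x_k} + a)

  with smoothing coefficient ``a`` and prior ``p`` (conventionally the
  global target mean).  Because only earlier samples contribute, the
  encoding of a sample never depends on its own target — no target
  leakage.

* :func:`fit_boosted` / :func:`predict_boosted` — a multiclass
  gradient-boosted decision-tree ensemble behind a fixed contract
  (deterministic given a seed; per-sample class probabilities summing to
  one).  The ensemble itself is scikit-learn's histogram
  gradient-boosting classifier; the pipeline's discriminant-score features
  are continuous, so the encoder above is exposed standalone rather than
  wired into the default feature path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier

__all__ = [
    "OrderedTSConfig",
    "BoostConfig",
    "BoostedModel",
    "ordered_target_statistic",
    "fit_boosted",
    "predict_boosted",
]


@dataclass(frozen=True)
class OrderedTSConfig:
    """Smoothing coefficient ``a``, prior ``p``, and the permutation seed."""

    smoothing_a: float = 1.0
    prior_p: float = 0.5
    permutation_seed: int = 0

    def __post_init__(self) -> None:
        if not self.smoothing_a > 0:
            raise ValueError("smoothing_a must be > 0")


def ordered_target_statistic(
    category_values: Sequence,
    targets: Sequence[float],
    config: Optional[OrderedTSConfig] = None,
    permutation: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Encode a categorical column by ordered target statistics.

    The first sample of the permutation (empty history) encodes to the
    prior ``p`` exactly, as does any sample whose category was never seen
    before it.  Returned in the original sample order.  ``permutation``
    overrides the seeded draw (useful for hand-checkable orderings).
    """
    config = config or OrderedTSConfig()
    cats = np.asarray(category_values, dtype=object)
    y = np.asarray(targets, dtype=float)
    if cats.shape[0] != y.shape[0]:
        raise ValueError("category_values and targets must have equal length")
    if permutation is not None:
        perm = np.asarray(permutation, dtype=int)
        if sorted(perm.tolist()) != list(range(cats.shape[0])):
            raise ValueError("permutation must be a permutation of range(n)")
    else:
        rng = np.random.default_rng(config.permutation_seed)
        perm = rng.permutation(cats.shape[0])
    a, p = config.smoothing_a, config.prior_p
    sums: dict = {}
    counts: dict = {}
    encoded = np.empty(cats.shape[0], dtype=float)
    for k in perm:
        c = cats[k]
        s = sums.get(c, 0.0)
        m = counts.get(c, 0)
        encoded[k] = (s + a * p) / (m + a)
        sums[c] = s + y[k]
        counts[c] = m + 1
    return encoded


@dataclass(frozen=True)
class BoostConfig:
    """Boosted-ensemble hyperparameters (tree count, depth, shrinkage)."""

    iterations: int = 500
    depth: int = 6
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")


@dataclass
class BoostedModel:
    estimator: HistGradientBoostingClassifier
    classes: np.ndarray
    config: BoostConfig


def fit_boosted(X: np.ndarray, y, config: Optional[BoostConfig] = None) -> BoostedModel:
    """Fit the multiclass boosted-tree ensemble; deterministic given seed."""
    config = config or BoostConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(str)
    if np.unique(y).size < 2:
        raise ValueError("boosted classifier needs at least 2 classes")
    est = HistGradientBoostingClassifier(
        max_iter=config.iterations,
        max_depth=config.depth,
        learning_rate=config.learning_rate,
        random_state=config.seed,
        early_stopping=False,
    )
    est.fit(X, y)
    return BoostedModel(estimator=est, classes=est.classes_, config=config)


def predict_boosted(model: BoostedModel, X: np.ndarray):
    """Predicted labels and class probabilities (rows sum to 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    proba = model.estimator.predict_proba(X)
    labels = model.classes[np.argmax(proba, axis=1)]
    return labels, proba
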