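"""Relief-F feature weighting and top-d selection.

The combined encodings (notably anything containing the 2400-dimensional
CKSAAP block) carry many uninformative features.  Relief-F scores each
feature by contrasting, for sampled instances, its separation from nearest
*misses* (other class) against nearest *hits* (same class): features that
differ across the class boundary but agree within a class get high weight.
The top-d features by weight are then retained, with d matching the
reduced dimensionalities used for each combined scheme (27 for AF-KNN,
952 for AF-CKSAAP, 939 for CKSAAP-KNN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.metrics import pairwise_distances

from oryzaphos.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

DEFAULT_TARGET_DIMS: dict[str, int] = {
    "AF-KNN": 27,
    "AF-CKSAAP": 952,
    "CKSAAP-KNN": 939,
}


@dataclass(frozen=True)
class FeatureWeights:
    """Per-feature relief-F weights and the descending-weight ranking.

    Ties in weight are broken by original layout order (stable sort), so the
    ranking is deterministic.
    """

    weights: np.ndarray
    ranking: np.ndarray

    @classmethod
    def from_weights(cls, weights: np.ndarray) -> "FeatureWeights":
        ranking = np.argsort(-weights, kind="stable")
        return cls(weights=weights, ranking=ranking)


@dataclass(frozen=True)
class SelectionSpec:
    """Relief-F configuration and per-scheme retained dimensions."""

    target_dims: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_DIMS)
    )
    neighbors: int = 10
    sample_size: int | None = None

    def target_dim(self, scheme: str, pre_dim: int) -> int:
        d = self.target_dims.get(scheme, pre_dim)
        if d > pre_dim:
            raise ConfigError(
                f"target dimension {d} for {scheme} exceeds pre-selection dimension {pre_dim}"
            )
        return d


def relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    neighbors: int = 10,
    sample_size: int | None = None,
    seed: int | None = None,
) -> FeatureWeights:
    """Two-class relief-F weights.

    For each sampled instance, the ``neighbors`` nearest hits and misses are
    found by Euclidean distance on range-scaled features, and each feature's
    weight accumulates mean miss-difference minus mean hit-difference, with
    per-feature differences scaled by the feature's range.  Zero-range
    (constant) features contribute no difference and keep weight exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ConfigError("X must be a 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise DataError("relief-F requires finite feature values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise DataError("relief-F needs two classes with at least 2 instances each")

    n, d = X.shape
    ranges = X.max(axis=0) - X.min(axis=0)
    zero_range = ranges == 0
    if zero_range.any():
        logger.info("%d zero-range features fixed at weight 0", int(zero_range.sum()))
    safe = np.where(zero_range, 1.0, ranges)
    Xs = (X - X.min(axis=0)) / safe
    Xs[:, zero_range] = 0.0

    rng = np.random.default_rng(seed)
    if sample_size is None or sample_size >= n:
        sampled = np.arange(n)
    else:
        sampled = rng.choice(n, size=sample_size, replace=False)

    dist = pairwise_distances(Xs)
    np.fill_diagonal(dist, np.inf)

    weights = np.zeros(d)
    m = sampled.size
    is_class0 = y == classes[0]
    idx_by_class = {0: np.flatnonzero(is_class0), 1: np.flatnonzero(~is_class0)}
    for i in sampled:
        own = 0 if is_class0[i] else 1
        hits_pool = idx_by_class[own]
        miss_pool = idx_by_class[1 - own]
        k_hit = min(neighbors, hits_pool.size - 1)
        k_miss = min(neighbors, miss_pool.size)
        hit_order = hits_pool[np.argsort(dist[i, hits_pool], kind="stable")[:k_hit]]
        miss_order = miss_pool[np.argsort(dist[i, miss_pool], kind="stable")[:k_miss]]
        hit_diff = np.abs(Xs[i] - Xs[hit_order]).mean(axis=0)
        miss_diff = np.abs(Xs[i] - Xs[miss_order]).mean(axis=0)
        weights += (miss_diff - hit_diff) / m
    weights[zero_range] = 0.0
    return FeatureWeights.from_weights(weights)


def select_top(
    X: np.ndarray,
    weights: FeatureWeights,
    target_dim: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Retain the ``target_dim`` highest-weighted features.

    Returns the reduced matrix and the retained column indices in original
    layout order (so downstream feature identifiers stay aligned).
    """
    X = np.asarray(X)
    d = weights.weights.size
    if target_dim < 1:
        raise ConfigError("target_dim must be >= 1")
    if target_dim > d:
        raise ConfigError(f"target_dim {target_dim} exceeds available features {d}")
    retained = np.sort(weights.ranking[:target_dim])
    return X[:, retained], retained
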