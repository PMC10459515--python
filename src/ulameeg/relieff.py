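"""ReliefF feature weighting and top-m selection.

ReliefF scores each feature by how well it separates nearby instances of
different classes.  For every visited instance the k nearest same-class
neighbors (hits) and k nearest other-class neighbors (misses) are found;
a feature's weight is decreased by its mean range-normalized absolute
difference to the hits and increased by the (class-prior weighted) mean
difference to the misses.  Informative features accumulate positive weight,
irrelevant ones hover near zero, and constant features score exactly zero.

Neighbor distances are Euclidean on range-normalized features — the same
normalization used in the diff terms — which makes the weights exactly
invariant to positive rescaling of any single feature column.  By default
every instance is visited once in index order, so the weights are fully
deterministic; a seeded random subsample is available for large instance
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "relieff_weights",
    "select_top",
    "run_relieff",
]


@dataclass
class FeatureMatrix:
    """Instances x features data with class labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (instances x features)")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y length must match number of instances")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains NaN or Inf")
        classes, counts = np.unique(self.y, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("each class needs at least 2 instances for ReliefF")
        self.classes_ = classes
        self.class_counts_ = counts


@dataclass
class SelectionResult:
    """ReliefF weights plus the ordered indices of the selected features."""

    weights: np.ndarray
    selected_idx: np.ndarray
    k_neighbors: int
    m: int


def relieff_weights(
    fm: FeatureMatrix,
    k: int = 5,
    iterations: int | str = "all",
    seed: int | None = None,
) -> np.ndarray:
    """Multi-neighbor ReliefF weights (one per feature).

    iterations="all" visits every instance once in index order (fully
    deterministic); an integer samples that many instances without
    replacement using ``seed``.  Each class must have more than k members.
    Multiclass inputs weight each miss class by its prior among the other
    classes.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    X, y = fm.X, fm.y
    n, d = X.shape
    if np.any(fm.class_counts_ <= k):
        small = fm.classes_[fm.class_counts_ <= k][0]
        raise ValueError(
            f"class {small!r} has {fm.class_counts_.min()} members; ReliefF with "
            f"k={k} needs more than k per class"
        )
    # range normalization; constant features get range 1 so their (zero)
    # diffs stay zero rather than 0/0
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng_safe = np.where(rng > 0, rng, 1.0)
    Xn = (X - lo) / rng_safe

    if iterations == "all":
        visit = np.arange(n)
    else:
        m_iter = int(iterations)
        if m_iter < 1:
            raise ValueError("iterations must be >= 1 or 'all'")
        gen = np.random.default_rng(seed)
        visit = gen.choice(n, size=min(m_iter, n), replace=False)

    priors = {c: cnt / n for c, cnt in zip(fm.classes_, fm.class_counts_)}
    # squared Euclidean distances on normalized features
    sq = np.einsum("ij,ij->i", Xn, Xn)
    w = np.zeros(d)
    for i in visit:
        dist = sq + sq[i] - 2.0 * (Xn @ Xn[i])
        dist[i] = np.inf
        same = y == y[i]
        hit_idx = np.flatnonzero(same)
        hit_idx = hit_idx[np.argsort(dist[hit_idx], kind="stable")[:k]]
        w -= np.abs(Xn[hit_idx] - Xn[i]).mean(axis=0)
        p_not = 1.0 - priors[y[i]]
        for c in fm.classes_:
            if c == y[i]:
                continue
            miss_idx = np.flatnonzero(y == c)
            miss_idx = miss_idx[np.argsort(dist[miss_idx], kind="stable")[:k]]
            w += (priors[c] / p_not) * np.abs(Xn[miss_idx] - Xn[i]).mean(axis=0)
    return w / len(visit)


def select_top(weights: np.ndarray, m: int = 7000) -> SelectionResult:
    """Indices of the m largest weights, descending; ties by ascending index."""
    weights = np.asarray(weights, dtype=np.float64)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m > weights.size:
        warnings.warn(
            f"requested {m} features but only {weights.size} exist; keeping all",
            stacklevel=2,
        )
        m = weights.size
    order = np.argsort(-weights, kind="stable")  # stable => ascending index on ties
    return SelectionResult(
        weights=weights, selected_idx=order[:m], k_neighbors=0, m=m
    )


def run_relieff(
    fm: FeatureMatrix,
    k: int = 5,
    m: int = 7000,
    iterations: int | str = "all",
    seed: int | None = None,
) -> SelectionResult:
    """Weights + top-m selection in one call."""
    w = relieff_weights(fm, k=k, iterations=iterations, seed=seed)
    res = select_top(w, m=m)
    return SelectionResult(
        weights=res.weights, selected_idx=res.selected_idx, k_neighbors=k, m=res.m
    )
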