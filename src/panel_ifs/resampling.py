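"""Stratified cross-validation folds and SMOTE class balancing.

Fold assignment is stratified per class (shuffled round-robin with a
rotating offset), so per-class counts across folds differ by at most one
and classes smaller than K are spread as evenly as possible.

SMOTE oversamples every minority class up to the majority-class count:
each synthetic sample is x + u * (z - x) with u ~ Uniform(0, 1), x a real
minority sample and z one of its k nearest same-class neighbors under
Euclidean distance.  Original rows are preserved verbatim and synthetic
rows are appended after them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["FoldAssignment", "stratified_folds", "smote_balance"]


@dataclass
class FoldAssignment:
    """Per-sample fold index in 0..K-1."""

    fold_of: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        if self.fold_of.size and (
            self.fold_of.min() < 0 or self.fold_of.max() >= self.K
        ):
            raise ValueError("fold indices must lie in 0..K-1")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def stratified_folds(labels: np.ndarray, K: int, seed: int) -> FoldAssignment:
    """Deterministic stratified K-fold partition.

    Each class's samples are shuffled and dealt to folds round-robin,
    starting from an offset that rotates with the running remainder so the
    overall fold sizes also stay balanced.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.shape[0]
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[i] = (offset + j) % K
        offset = (offset + len(idx)) % K
    return FoldAssignment(fold_of=fold_of, K=K)


def smote_balance(
    values: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every class up to the majority-class count.

    When a class has fewer than ``k_neighbors + 1`` members, the number of
    neighbors is reduced to class size - 1.  A class of a single sample has
    no neighbor to interpolate toward and raises a ValueError.  An already
    balanced input is returned unchanged (copies of the originals).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels lengths differ")
    if k_neighbors < 1:
        raise ValueError(f"k_neighbors must be >= 1, got {k_neighbors}")
    counts = np.bincount(labels)
    present = np.flatnonzero(counts)
    if np.any(counts[present] == 1):
        bad = np.flatnonzero(counts == 1).tolist()
        raise ValueError(f"class(es) with a single sample cannot be oversampled: {bad}")
    target = int(counts.max())

    rng = np.random.default_rng(seed)
    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    for cls in present:
        need = target - int(counts[cls])
        if need == 0:
            continue
        X = values[labels == cls]
        k = min(k_neighbors, X.shape[0] - 1)
        # +1 then drop self from each neighbor list
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
        base = rng.integers(0, X.shape[0], size=need)
        pick = rng.integers(0, k, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        x = X[base]
        z = X[neigh[base, pick]]
        new_rows.append(x + u[:, None] * (z - x))
        new_labels.extend([int(cls)] * need)

    if not new_rows:
        return values.copy(), labels.copy()
    return (
        np.vstack([values] + new_rows),
        np.concatenate([labels, np.array(new_labels, dtype=int)]),
    )
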