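"""Kennard-Stone splitting and venetian-blinds cross-validation folds."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SplitResult:
    """Train/test row indices (train in selection order, test ascending)."""

    train_indices: tuple
    test_indices: tuple

    def to_frame(self, sample_ids=None):
        """Two-column audit table (sample_id, partition)."""
        import pandas as pd

        n = len(self.train_indices) + len(self.test_indices)
        ids = list(sample_ids) if sample_ids is not None else list(range(n))
        part = {}
        for i in self.train_indices:
            part[i] = "train"
        for i in self.test_indices:
            part[i] = "test"
        return pd.DataFrame(
            {"sample_id": [ids[i] for i in range(n)], "partition": [part[i] for i in range(n)]}
        )


@dataclass(frozen=True)
class CVFolds:
    """Per-sample fold ids in 0..k-1."""

    fold_of: tuple

    @property
    def k(self) -> int:
        return int(max(self.fold_of)) + 1

    def splits(self):
        """Yield (train_rows, val_rows) index arrays per fold."""
        fold = np.asarray(self.fold_of)
        for f in range(self.k):
            val = np.flatnonzero(fold == f)
            yield np.flatnonzero(fold != f), val


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def kennard_stone(X, fraction: float = 0.7) -> SplitResult:
    """Deterministic max-min-distance train/test split.

    Seeds the selection with the pair of samples at maximal Euclidean
    distance, then repeatedly adds the sample whose minimal distance to
    the selected set is maximal, until ``round(fraction * n)`` training
    samples (rounding half away from zero) are chosen.  Ties break to
    the lowest row index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n_train = _round_half_away(fraction * n)
    if n_train < 2 or n_train >= n:
        raise ValueError(
            f"fraction {fraction} on n={n} gives train size {n_train}; "
            "both partitions must be non-empty (train >= 2)"
        )
    D = cdist(X, X)
    i, j = np.unravel_index(np.argmax(D), D.shape)  # first (lowest) on ties
    selected = [int(min(i, j)), int(max(i, j))]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    test = tuple(sorted(set(range(n)) - set(selected)))
    return SplitResult(tuple(selected), test)


def venetian_blinds(n: int, k: int = 10) -> CVFolds:
    """Fold assignment by row order: sample ``i`` goes to fold ``i mod k``."""
    if k < 2 or n < k:
        raise ValueError(f"venetian blinds needs n >= k >= 2 (got n={n}, k={k})")
    return CVFolds(tuple(int(i % k) for i in range(n)))
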