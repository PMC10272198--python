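"""Shared class-statistics and Mahalanobis-distance helpers.

High-dimensional spectra make raw sample covariances singular; whenever
a covariance has condition number above 1e10 a ridge
``lambda = 1e-8 * trace(C) / dim`` is added to the diagonal.  The
applied ridge is always recorded by the callers.
"""

from __future__ import annotations

import numpy as np

COND_THRESHOLD = 1e10
RIDGE_SCALE = 1e-8


def ridge_covariance(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (possibly ridged covariance, applied lambda)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    d = C.shape[0]
    cond = np.linalg.cond(C)
    if np.isfinite(cond) and cond <= COND_THRESHOLD:
        return C, 0.0
    tr = float(np.trace(C))
    lam = RIDGE_SCALE * tr / d if tr > 0 else RIDGE_SCALE
    return C + lam * np.eye(d), lam


def class_statistics(X, y):
    """Per-class means/covariances and the pooled covariance.

    Returns ``(classes, means, covs, pooled)`` with classes in sorted
    order, per-class covariances using divisor ``n_k - 1`` and
    ``pooled = sum_k (n_k - 1) C_k / (n - K)``.  No ridge is applied
    here.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    means, covs, dof = [], [], 0
    pooled = np.zeros((X.shape[1], X.shape[1]))
    for c in classes:
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples; covariance undefined")
        means.append(rows.mean(axis=0))
        Ck = np.cov(rows, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
        covs.append(Ck)
        pooled += (rows.shape[0] - 1) * Ck
        dof += rows.shape[0] - 1
    pooled /= X.shape[0] - classes.size
    return classes, np.asarray(means), covs, pooled


def mahalanobis_sq(X, mean, C) -> np.ndarray:
    """Squared Mahalanobis distances of rows of X to ``mean`` under ``C``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    diff = X - np.asarray(mean, dtype=float)
    sol = np.linalg.solve(np.atleast_2d(C), diff.T)
    return np.einsum("ij,ji->i", diff, sol)
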