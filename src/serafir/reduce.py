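"""Feature reduction: principal component analysis and the successive
projections algorithm (SPA).

PCA decomposes the mean-centered spectral matrix as ``X = T P^T + E``
(scores ``T``, orthonormal loadings ``P``, residual ``E``) via the
singular value decomposition.  SPA instead selects a small subset of
original wavenumbers: starting from every column it grows chains of
minimally collinear variables by successive orthogonal projections,
then scores every chain prefix on a validation set with the
Mahalanobis cost

    G = (1/Nv) * sum_n r2(x_n, m_true) / min_wrong r2(x_n, m_wrong)

and returns the subset of minimal G (lower G = better separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mahalanobis import class_statistics, mahalanobis_sq, ridge_covariance


@dataclass
class PCAModel:
    loadings: np.ndarray  # (p, k), orthonormal columns
    scores: np.ndarray  # (n, k) training scores
    explained_variance_fraction: np.ndarray  # (k,)
    n_components: int
    training_grid: np.ndarray | None = None
    column_means: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "kind": "pca",
            "n_components": int(self.n_components),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "training_grid": None
            if self.training_grid is None
            else self.training_grid.tolist(),
        }


@dataclass
class SPASelection:
    selected_indices: tuple
    cost_G: list = field(default_factory=list)  # [(subset tuple, G), ...]
    n_selected: int = 0

    def __post_init__(self) -> None:
        self.selected_indices = tuple(int(i) for i in self.selected_indices)
        self.n_selected = len(self.selected_indices)


def fit_pca(Xc, n_components: int, training_grid=None) -> PCAModel:
    """Fit PCA by SVD of the centered matrix ``Xc``.

    Explained-variance fractions are ``sigma_j^2 / sum_i sigma_i^2``
    over *all* singular values.  Sign convention: the largest-magnitude
    element of each loading column is positive.
    """
    Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
    n, p = Xc.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = (s[0] * max(n, p) * np.finfo(float).eps) if s.size and s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the achievable rank {rank}"
        )
    P = Vt[:n_components].T.copy()
    for j in range(n_components):
        if P[np.argmax(np.abs(P[:, j])), j] < 0:
            P[:, j] = -P[:, j]
    T = Xc @ P
    total = float(np.sum(s**2))
    evf = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    grid = None if training_grid is None else np.asarray(training_grid, dtype=float)
    return PCAModel(P, T, evf, n_components, grid)


def project(model: PCAModel, Xc_new, grid=None) -> np.ndarray:
    """Project new centered rows onto the fitted loadings."""
    Xc_new = np.atleast_2d(np.asarray(Xc_new, dtype=float))
    if grid is not None and model.training_grid is not None:
        if not np.array_equal(np.asarray(grid, dtype=float), model.training_grid):
            raise ValueError("wavenumber grid does not match the PCA training grid")
    if Xc_new.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"feature dimension {Xc_new.shape[1]} != training dimension "
            f"{model.loadings.shape[0]}"
        )
    return Xc_new @ model.loadings


def spa_cost_g(X_val, y_val, classes, means, pooled_cov) -> float:
    """Mahalanobis separation cost G over a validation set.

    ``classes``/``means``/``pooled_cov`` come from training data
    (:func:`serafir._mahalanobis.class_statistics`); the pooled
    covariance is ridged on demand.  Every training class must appear
    in ``y_val`` and every validation label must be a training class.
    """
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_val = np.asarray(y_val)
    classes = np.asarray(classes)
    if classes.size < 2:
        raise ValueError("need statistics for at least 2 classes")
    present = set(y_val.tolist())
    missing = [c for c in classes.tolist() if c not in present]
    if missing:
        raise ValueError(f"validation set lacks class(es) {missing}")
    unknown = sorted(present - set(classes.tolist()))
    if unknown:
        raise ValueError(f"validation label(s) {unknown} absent from training statistics")
    C, _ = ridge_covariance(pooled_cov)
    d2 = np.stack([mahalanobis_sq(X_val, m, C) for m in means], axis=1)  # (Nv, K)
    g = np.empty(len(y_val))
    for n, lab in enumerate(y_val):
        k = int(np.flatnonzero(classes == lab)[0])
        num = d2[n, k]
        den = np.min(np.delete(d2[n], k))
        if den == 0.0:
            g[n] = 0.0 if num == 0.0 else np.inf
        else:
            g[n] = num / den
    return float(np.mean(g))


def spa_chains(X_train, max_vars: int) -> list[list[int]]:
    """Successive-projections candidate chains from every starting column.

    From each start the chain repeatedly appends the column of maximal
    norm after orthogonal projection onto the complement of the span of
    the chosen columns (computed on the training matrix).  Columns that
    become numerically collinear with the chain (projected norm below
    1e-10 of the largest original column norm) are never chosen.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    n, p = X.shape
    if max_vars < 1:
        raise ValueError("max_vars must be >= 1")
    norms0 = np.linalg.norm(X, axis=0)
    thresh = 1e-10 * (norms0.max() if norms0.size else 1.0)
    chains = []
    for start in range(p):
        R = X.copy()
        chain = [start]
        nrm = np.linalg.norm(R[:, start])
        if nrm > 0:
            q = R[:, start] / nrm
            R -= np.outer(q, q @ R)
        while len(chain) < max_vars:
            col_norms = np.linalg.norm(R, axis=0)
            col_norms[chain] = -1.0
            nxt = int(np.argmax(col_norms))
            if col_norms[nxt] <= thresh:
                break
            chain.append(nxt)
            q = R[:, nxt] / col_norms[nxt]
            R -= np.outer(q, q @ R)
        chains.append(chain)
    return chains


def spa_candidates(X_train, y_train, X_val, y_val, max_vars: int) -> list[tuple[tuple, float]]:
    """Score every chain prefix by G; returns [(subset, G), ...]."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    n, p = X_train.shape
    if not 1 <= max_vars <= min(n - 1, p):
        raise ValueError(
            f"max_vars must be within 1..min(n_train-1, p) = {min(n - 1, p)}"
        )
    scored = []
    seen = set()
    for chain in spa_chains(X_train, max_vars):
        for L in range(1, len(chain) + 1):
            subset = tuple(chain[:L])
            key = frozenset(subset)
            if key in seen:
                continue
            seen.add(key)
            classes, means, _, pooled = class_statistics(X_train[:, subset], y_train)
            G = spa_cost_g(np.atleast_2d(X_val)[:, subset], y_val, classes, means, pooled)
            scored.append((subset, G))
    return scored


def spa_select(X_train, y_train, X_val, y_val, max_vars: int) -> SPASelection:
    """Return the chain-prefix subset of minimal validation cost G.

    Ties break to the smaller subset, then to the earlier candidate in
    chain order (deterministic).
    """
    scored = spa_candidates(X_train, y_train, X_val, y_val, max_vars)
    best = min(enumerate(scored), key=lambda t: (t[1][1], len(t[1][0]), t[0]))
    return SPASelection(best[1][0], cost_G=scored)
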