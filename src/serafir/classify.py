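"""Discriminant classifiers and a soft-margin RBF support vector machine.

LDA and QDA are used in their *non-Bayesian* form: the classification
score of sample ``x`` for class ``k`` is the plain squared Mahalanobis
distance

    L_ik = (x - xbar_k)^T C_pooled^-1 (x - xbar_k)          (LDA)
    Q_ik = (x - xbar_k)^T C_k^-1      (x - xbar_k)          (QDA)

and a sample is assigned to the class of minimal score.  Note this
omits the log-determinant and prior terms of textbook Bayesian QDA
posteriors - a deliberate choice of score, not an approximation.

The SVM solves the standard soft-margin dual

    max  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t. 0 <= a_i <= C,  sum_i a_i y_i = 0

with the RBF kernel ``K(x, z) = exp(-gamma ||x - z||^2)`` by a
deterministic SMO (maximal-violating-pair working set, ties to the
lowest index), and predicts ``sign(sum_i a_i y_i K(x_i, z) + b)`` with
``sign(0) = +1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._mahalanobis import class_statistics, mahalanobis_sq, ridge_covariance
from .model_selection import CVFolds

#: Default cross-validation lattice: C = 2^-5..2^15, gamma = 2^-15..2^3,
#: both in multiplicative steps of 4.
DEFAULT_SVM_GRID = tuple(
    (2.0**ce, 2.0**ge) for ce in range(-5, 16, 2) for ge in range(-15, 4, 2)
)


class SVMConvergenceError(RuntimeError):
    """SMO failed to reach the KKT tolerance within the iteration cap."""

    def __init__(self, n_iter: int, gap: float, tol: float):
        self.n_iter, self.gap, self.tol = n_iter, gap, tol
        super().__init__(
            f"SMO did not converge: KKT gap {gap:.3e} > tol {tol:.1e} "
            f"after {n_iter} iterations"
        )


# ---------------------------------------------------------------- LDA / QDA


@dataclass
class DiscriminantModel:
    kind: str  # "lda" or "qda"
    classes: np.ndarray
    class_means: np.ndarray  # (K, d)
    pooled_cov: np.ndarray | None = None
    class_covs: list | None = None
    ridge_lambda: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "classes": self.classes.tolist(),
            "class_means": self.class_means.tolist(),
            "pooled_cov": None if self.pooled_cov is None else self.pooled_cov.tolist(),
            "class_covs": None
            if self.class_covs is None
            else [C.tolist() for C in self.class_covs],
            "ridge_lambda": {str(k): v for k, v in self.ridge_lambda.items()},
        }


def fit_discriminant(X, y, kind: str = "lda") -> DiscriminantModel:
    """Fit class means and (pooled or per-class) covariances.

    ``C_pooled = sum_k (n_k - 1) C_k / (n - K)`` with each ``C_k`` using
    divisor ``n_k - 1``.  Ill-conditioned covariances receive the ridge
    recorded in ``ridge_lambda``.
    """
    if kind not in ("lda", "qda"):
        raise ValueError("kind must be 'lda' or 'qda'")
    classes, means, covs, pooled = class_statistics(X, y)
    ridge: dict = {}
    if kind == "lda":
        pooled, lam = ridge_covariance(pooled)
        ridge["pooled"] = lam
        return DiscriminantModel(kind, classes, means, pooled_cov=pooled, ridge_lambda=ridge)
    ridged = []
    for c, Ck in zip(classes, covs):
        Ck, lam = ridge_covariance(Ck)
        ridged.append(Ck)
        ridge[c] = lam
    return DiscriminantModel(kind, classes, means, class_covs=ridged, ridge_lambda=ridge)


def discriminant_score(model: DiscriminantModel, X, k=None) -> np.ndarray:
    """Squared Mahalanobis score(s) of rows of X.

    With ``k`` (a class label) returns the per-row score for that
    class; otherwise an (n, K) matrix over all classes in
    ``model.classes`` order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.class_means.shape[1]}"
        )
    covs = (
        [model.pooled_cov] * len(model.classes)
        if model.kind == "lda"
        else model.class_covs
    )
    S = np.stack(
        [mahalanobis_sq(X, m, C) for m, C in zip(model.class_means, covs)], axis=1
    )
    if k is None:
        return S
    idx = np.flatnonzero(model.classes == k)
    if idx.size == 0:
        raise ValueError(f"unknown class {k!r}")
    return S[:, int(idx[0])]


def classify_discriminant(model: DiscriminantModel, X) -> np.ndarray:
    """Assign each row to the class of minimal score (ties: first class)."""
    S = discriminant_score(model, X)
    return model.classes[np.argmin(S, axis=1)]


# ----------------------------------------------------------------------- SVM


def rbf_kernel(A, B, gamma: float) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return np.exp(-gamma * cdist(A, B, "sqeuclidean"))


@dataclass
class SVMModel:
    support_vectors: np.ndarray
    alphas: np.ndarray  # multipliers of the support vectors
    labels: np.ndarray  # +-1 of the support vectors
    bias: float
    gamma: float
    C: float
    n_iter: int = 0
    kkt_gap: float = 0.0

    def to_dict(self) -> dict:
        return {
            "kind": "svm",
            "support_vectors": self.support_vectors.tolist(),
            "alphas": self.alphas.tolist(),
            "labels": self.labels.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "C": self.C,
        }


def fit_svm(X, y, C: float, gamma: float, tol: float = 1e-5, max_iter: int | None = None) -> SVMModel:
    """Solve the soft-margin RBF dual by deterministic SMO.

    Working pairs are chosen deterministically: ``i`` as the maximal
    KKT violator, ``j`` by the second-order (largest dual decrease)
    rule, ties to the lowest index; convergence when the KKT gap drops
    to ``tol``.
    The bias is the average of ``y_i - sum_j a_j y_j K(x_j, x_i)`` over
    unbounded support vectors (``0 < a_i < C``), or the midpoint of the
    final KKT bounds when none exist.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be +-1")
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    n = len(y)
    K = rbf_kernel(X, X, gamma)
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 a^T Q a - e^T a
    if max_iter is None:
        max_iter = max(100_000, 1_000 * n)

    snap = 1e-12 * C  # multipliers this close to a bound are set exactly on it
    diagK = np.ascontiguousarray(np.diag(K))

    for it in range(max_iter):
        yg = -y * grad
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        up_vals = np.where(up, yg, -np.inf)
        low_vals = np.where(low, yg, np.inf)
        i = int(np.argmax(up_vals))
        m, M = up_vals[i], float(np.min(low_vals))
        gap = m - M
        if gap <= tol:
            break
        # second-order choice of j: largest decrease of the dual objective
        diff = m - yg
        a_vec = np.maximum(K[i, i] + diagK - 2.0 * K[i], 1e-12)
        score = np.where(low & (diff > 0), -(diff**2) / a_vec, np.inf)
        j = int(np.argmin(score))
        a = K[i, i] + K[j, j] - 2.0 * K[i, j]
        t = (m - yg[j]) / max(a, 1e-12)
        # box limits along the feasible direction (d_i = y_i, d_j = -y_j)
        t = min(t, (C - alpha[i]) if y[i] > 0 else alpha[i])
        t = min(t, alpha[j] if y[j] > 0 else (C - alpha[j]))
        dai, daj = y[i] * t, -y[j] * t
        new_i = min(max(alpha[i] + dai, 0.0), C)
        new_j = min(max(alpha[j] + daj, 0.0), C)
        if new_i < snap:
            new_i = 0.0
        elif new_i > C - snap:
            new_i = C
        if new_j < snap:
            new_j = 0.0
        elif new_j > C - snap:
            new_j = C
        dai, daj = new_i - alpha[i], new_j - alpha[j]
        alpha[i], alpha[j] = new_i, new_j
        grad += Q[:, i] * dai + Q[:, j] * daj
    else:
        raise SVMConvergenceError(max_iter, float(gap), tol)

    G = K @ (alpha * y)  # decision values without bias
    unbounded = (alpha > 1e-8) & (alpha < C - 1e-8)
    if unbounded.any():
        b = float(np.mean(y[unbounded] - G[unbounded]))
    else:
        b = float((m + M) / 2.0)
    sv = alpha > 1e-8
    return SVMModel(
        support_vectors=X[sv].copy(),
        alphas=alpha[sv].copy(),
        labels=y[sv].copy(),
        bias=b,
        gamma=gamma,
        C=C,
        n_iter=it + 1,
        kkt_gap=float(m - M),
    )


def predict_svm(model: SVMModel, Z) -> np.ndarray:
    """Labels ``sign(sum_i a_i y_i K(x_i, z) + b)`` with sign(0) -> +1."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if model.support_vectors.size and Z.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"feature dimension {Z.shape[1]} != model dimension "
            f"{model.support_vectors.shape[1]}"
        )
    dec = decision_svm(model, Z)
    return np.where(dec >= 0.0, 1.0, -1.0)


def decision_svm(model: SVMModel, Z) -> np.ndarray:
    if model.support_vectors.shape[0] == 0:
        return np.full(np.atleast_2d(Z).shape[0], model.bias)
    Kz = rbf_kernel(Z, model.support_vectors, model.gamma)
    return Kz @ (model.alphas * model.labels) + model.bias


def tune_svm(
    X, y, folds: CVFolds, grid=DEFAULT_SVM_GRID, tol: float = 1e-3
) -> tuple[float, float]:
    """Pick the (C, gamma) lattice point maximising mean CV accuracy.

    Ties break to the smallest C, then the smallest gamma.  Folds whose
    training part contains a single class are skipped with a warning.
    ``tol`` is the working SMO tolerance used during the search; lattice
    corners with a near-singular Gram matrix make the dual optimum
    nearly flat, where tighter tolerances cost many iterations without
    changing predictions.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    best, best_acc = None, -np.inf
    for C, gamma in sorted(grid):
        accs = []
        for train_rows, val_rows in folds.splits():
            if len(set(y[train_rows])) < 2:
                warnings.warn(
                    "skipping single-class CV fold during SVM tuning", stacklevel=2
                )
                continue
            model = fit_svm(X[train_rows], y[train_rows], C, gamma, tol=tol)
            pred = predict_svm(model, X[val_rows])
            accs.append(float(np.mean(pred == y[val_rows])))
        acc = float(np.mean(accs)) if accs else -np.inf
        if acc > best_acc:
            best, best_acc = (C, gamma), acc
    assert best is not None
    return best
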