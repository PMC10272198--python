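import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from serafir.classify import (
    DiscriminantModel,
    classify_discriminant,
    discriminant_score,
    fit_discriminant,
    fit_svm,
    predict_svm,
    rbf_kernel,
    tune_svm,
)
from serafir.model_selection import venetian_blinds


def two_class_data(seed, n=12, d=3, sep=2.0):
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"] * (n // 2), dtype=object)
    X = rng.normal(size=(n, d))
    X[y == "b", 0] += sep
    return X, y


class TestFitDiscriminant:
    def test_degenerate_means_equal_the_points(self):
        rng = np.random.default_rng(0)
        X = np.repeat([[1.0, 2.0], [5.0, -1.0]], 3, axis=0) + rng.normal(0, 1e-9, (6, 2))
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        m = fit_discriminant(X, y, "lda")
        np.testing.assert_allclose(m.class_means, [[1, 2], [5, -1]], atol=1e-8)

    def test_pooling_identity_for_equal_class_covariances(self):
        base = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [1.0, 2.0]])
        X = np.vstack([base, base + 10.0])
        y = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        m = fit_discriminant(X, y, "lda")
        np.testing.assert_allclose(m.pooled_cov, np.cov(base, rowvar=False, ddof=1), atol=1e-12)

    def test_pooled_matches_hand_weighted_average(self):
        Xa = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        Xb = np.array([[5.0, 5.0], [9.0, 5.0], [5.0, 9.0], [9.0, 9.0]])
        X, y = np.vstack([Xa, Xb]), np.array(["a"] * 3 + ["b"] * 4, dtype=object)
        m = fit_discriminant(X, y, "lda")
        hand = (2 * np.cov(Xa, rowvar=False, ddof=1) + 3 * np.cov(Xb, rowvar=False, ddof=1)) / 5
        np.testing.assert_allclose(m.pooled_cov, hand, atol=1e-12)

    def test_single_sample_class_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b"], dtype=object)
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_discriminant(X, y, "qda")


class TestDiscriminantScore:
    def test_score_at_class_mean_is_zero(self):
        X, y = two_class_data(1)
        m = fit_discriminant(X, y, "lda")
        for k, mean in zip(m.classes, m.class_means):
            assert discriminant_score(m, mean[None, :], k)[0] == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_reduces_to_euclidean(self):
        m = DiscriminantModel(
            "lda",
            np.array(["a", "b"], dtype=object),
            np.array([[0.0, 0.0], [10.0, 10.0]]),
            pooled_cov=np.eye(2),
        )
        s = discriminant_score(m, [[3.0, 4.0]], "a")[0]
        assert s == pytest.approx(25.0)

    def test_hand_inverted_diagonal_covariance(self):
        """C = diag(2, 1), x - mean = (2, 3) -> 4/2 + 9/1 = 11."""
        m = DiscriminantModel(
            "lda",
            np.array(["a", "b"], dtype=object),
            np.array([[0.0, 0.0], [100.0, 100.0]]),
            pooled_cov=np.array([[2.0, 0.0], [0.0, 1.0]]),
        )
        assert discriminant_score(m, [[2.0, 3.0]], "a")[0] == pytest.approx(11.0)

    def test_qda_equals_lda_under_equal_covariances(self):
        base = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 2.0], [1.5, 1.5], [2.0, 0.0]])
        X = np.vstack([base, base + [8.0, -3.0]])
        y = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        lda = fit_discriminant(X, y, "lda")
        qda = fit_discriminant(X, y, "qda")
        Z = np.random.default_rng(4).normal(size=(20, 2)) * 3
        np.testing.assert_allclose(
            discriminant_score(lda, Z), discriminant_score(qda, Z), atol=1e-10
        )

    def test_mahalanobis_affine_invariance(self):
        """Classification is unchanged under a common invertible affine
        map when covariances are refitted."""
        rng = np.random.default_rng(9)
        X, y = two_class_data(9, n=20)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        Z = rng.normal(size=(30, 3)) * 2
        for kind in ("lda", "qda"):
            m1 = fit_discriminant(X, y, kind)
            m2 = fit_discriminant(X @ A.T + b, y, kind)
            np.testing.assert_array_equal(
                classify_discriminant(m1, Z), classify_discriminant(m2, Z @ A.T + b)
            )


def qp_oracle_svm(X, y, C, gamma):
    """Generic QP solve of the soft-margin dual (independent of SMO)."""
    K = np.exp(-gamma * cdist(X, X, "sqeuclidean"))
    Q = (y[:, None] * y[None, :]) * K
    n = len(y)

    def f(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(
        f,
        np.zeros(n),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    alpha = res.x
    unb = (alpha > 1e-6) & (alpha < C - 1e-6)
    G = K @ (alpha * y)
    v = y - G  # KKT-admissible bias candidates
    if unb.any():
        b = float(np.mean(v[unb]))
    else:
        # all multipliers on a bound: the bias is only box-constrained;
        # take the midpoint of its admissible interval (as the solver does)
        up = ((y > 0) & (alpha < C - 1e-6)) | ((y < 0) & (alpha > 1e-6))
        low = ((y > 0) & (alpha > 1e-6)) | ((y < 0) & (alpha < C - 1e-6))
        b = float((v[up].max() + v[low].min()) / 2.0)
    return alpha, b


def dual_objective(model):
    K = rbf_kernel(model.support_vectors, model.support_vectors, model.gamma)
    ay = model.alphas * model.labels
    return model.alphas.sum() - 0.5 * ay @ K @ ay


class TestSvm:
    def test_kernel_is_one_at_zero_distance(self):
        x = np.array([[1.0, -2.0, 0.5]])
        for gamma in (0.01, 1.0, 50.0):
            assert rbf_kernel(x, x, gamma)[0, 0] == pytest.approx(1.0)

    def test_two_point_instance_solved_in_closed_form(self):
        """One point per class: both become support vectors with equal
        multipliers alpha = 1/(1 - K12); the boundary is the midpoint."""
        X = np.array([[0.0], [2.0]])
        y = np.array([1.0, -1.0])
        gamma = 0.3
        m = fit_svm(X, y, C=100.0, gamma=gamma)
        k12 = np.exp(-gamma * 4.0)
        assert len(m.alphas) == 2
        np.testing.assert_allclose(m.alphas, [1 / (1 - k12)] * 2, atol=1e-4)
        assert predict_svm(m, [[0.9]])[0] == 1.0
        assert predict_svm(m, [[1.1]])[0] == -1.0
        # the decision value vanishes at the midpoint (up to round-off)
        from serafir.classify import decision_svm

        assert abs(decision_svm(m, [[1.0]])[0]) < 1e-9

    def test_sign_zero_tie_resolves_to_positive(self):
        """An exactly-zero decision value classifies as +1 (documented)."""
        from serafir.classify import SVMModel

        m = SVMModel(
            support_vectors=np.array([[-1.0], [1.0]]),
            alphas=np.array([1.0, 1.0]),
            labels=np.array([1.0, -1.0]),
            bias=0.0,
            gamma=1.0,
            C=10.0,
        )
        # symmetric kernel sums cancel exactly at the origin
        assert predict_svm(m, [[0.0]])[0] == 1.0

    def test_training_points_of_separable_pair_keep_labels(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([1.0, -1.0])
        m = fit_svm(X, y, C=100.0, gamma=0.3)
        np.testing.assert_array_equal(predict_svm(m, X), y)

    def test_xor_pattern_separated_nonlinearly(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        m = fit_svm(X, y, C=1000.0, gamma=10.0)
        np.testing.assert_array_equal(predict_svm(m, X), y)

    def test_dual_feasibility_at_solution(self):
        X, ylab = two_class_data(3, n=14)
        y = np.where(ylab == "a", 1.0, -1.0)
        m = fit_svm(X, y, C=10.0, gamma=0.5)
        assert abs(np.sum(m.alphas * m.labels)) < 1e-6
        assert np.all(m.alphas >= 0) and np.all(m.alphas <= 10.0)
        assert m.kkt_gap <= 1e-5

    @pytest.mark.parametrize("seed", range(20))
    def test_agreement_with_qp_oracle(self, seed):
        """SMO and a generic QP solver agree: equal dual objective and
        identical predictions away from the decision boundary."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13)) // 2 * 2
        X = rng.normal(size=(n, 2))
        y = np.array([1.0, -1.0] * (n // 2))
        X[y > 0] += rng.uniform(0.5, 2.0)
        C, gamma = float(rng.choice([1.0, 10.0])), float(rng.choice([0.3, 1.0]))
        m = fit_svm(X, y, C, gamma)
        alpha_o, b_o = qp_oracle_svm(X, y, C, gamma)
        K = np.exp(-gamma * cdist(X, X, "sqeuclidean"))
        obj_o = alpha_o.sum() - 0.5 * (alpha_o * y) @ K @ (alpha_o * y)
        assert dual_objective(m) >= obj_o - 1e-5 * max(1.0, abs(obj_o))
        Z = rng.normal(size=(40, 2)) * 1.5
        from serafir.classify import decision_svm

        dec_o = np.exp(-gamma * cdist(Z, X, "sqeuclidean")) @ (alpha_o * y) + b_o
        ours = decision_svm(m, Z)
        clear = np.abs(dec_o) > 1e-3
        np.testing.assert_array_equal(np.sign(ours[clear]), np.sign(dec_o[clear]))

    def test_invalid_inputs_rejected(self):
        X = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError, match="both classes"):
            fit_svm(X, np.array([1.0, 1.0]), 1.0, 1.0)
        with pytest.raises(ValueError, match="positive"):
            fit_svm(X, np.array([1.0, -1.0]), -1.0, 1.0)
        m = fit_svm(X, np.array([1.0, -1.0]), 1.0, 1.0)
        with pytest.raises(ValueError, match="dimension"):
            predict_svm(m, np.zeros((1, 2)))


class TestTuneSvm:
    def test_single_point_grid_returned(self):
        X, ylab = two_class_data(0)
        y = np.where(ylab == "a", 1.0, -1.0)
        folds = venetian_blinds(len(y), 3)
        assert tune_svm(X, y, folds, grid=[(2.0, 0.5)]) == (2.0, 0.5)

    def test_chosen_point_attains_maximal_cv_accuracy(self):
        """Argmax contract checked against an independent fold loop."""
        X, ylab = two_class_data(8, n=20, sep=3.0)
        y = np.where(ylab == "a", 1.0, -1.0)
        folds = venetian_blinds(len(y), 5)
        grid = [(0.01, 1e-6), (1.0, 0.1), (10.0, 0.5)]

        def cv_acc(C, gamma):
            accs = []
            for tr, va in folds.splits():
                m = fit_svm(X[tr], y[tr], C, gamma, tol=1e-3)
                accs.append(np.mean(predict_svm(m, X[va]) == y[va]))
            return float(np.mean(accs))

        best = tune_svm(X, y, folds, grid=grid)
        assert cv_acc(*best) == max(cv_acc(C, g) for C, g in grid)

    def test_accuracy_tie_breaks_to_smallest_c_then_gamma(self):
        X, ylab = two_class_data(8, n=20, sep=5.0)
        y = np.where(ylab == "a", 1.0, -1.0)
        folds = venetian_blinds(len(y), 5)
        # widely separated classes: every point below scores identically
        grid = [(4.0, 0.5), (2.0, 1.0), (2.0, 0.5)]
        assert tune_svm(X, y, folds, grid=grid) == (2.0, 0.5)

    def test_single_class_fold_skipped_with_warning(self):
        """A pathological fold layout (one class concentrated in the
        held-in rows) is skipped, not fatal."""
        X = np.array([[0.0], [0.1], [5.0], [5.1], [0.2], [5.2]])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        from serafir.model_selection import CVFolds

        folds = CVFolds((0, 0, 1, 1, 0, 0))  # fold 0 leaves only class -1
        with pytest.warns(UserWarning, match="single-class"):
            C, gamma = tune_svm(X[:, :], y, folds, grid=[(1.0, 0.5)])
        assert (C, gamma) == (1.0, 0.5)
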