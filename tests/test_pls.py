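"""NIPALS PLS core: oracle equivalences (OLS, LOO, covariance eigenvalues,
scikit-learn), score orthogonality, CV hygiene, and the discriminant layer."""

import numpy as np
import pytest

from roastchem.pls import (
    classification_metrics,
    fit_pls,
    one_hot,
    pca,
    plsda_assign,
    plsda_fit,
    predict,
    select_n_lv,
    venetian_blinds_cv,
    venetian_blinds_folds,
    CVResult,
)


def random_xy(seed=0, n=20, p=6, m=1, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + noise * rng.normal(size=(n, m))
    return X, Y


class TestPCA:
    def test_rank_one_matrix_first_pc_explains_everything(self):
        u = np.linspace(1, 3, 8)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        scores, loadings, explained = pca(u @ v, n_pc=2)
        assert explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction(self):
        X = np.random.default_rng(1).normal(size=(10, 4))
        scores, loadings, _ = pca(X, n_pc=4)
        Xc = X - X.mean(axis=0)
        assert np.allclose(scores @ loadings.T, Xc, atol=1e-10)

    def test_explained_variance_matches_covariance_eigenvalues(self):
        X = np.random.default_rng(2).normal(size=(15, 5))
        _, _, explained = pca(X, n_pc=5)
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (len(X) - 1)))[::-1]
        assert np.allclose(explained, eig / eig.sum(), atol=1e-10)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca(np.ones((4, 3)), n_pc=2)


class TestFitPLS:
    def test_exact_linear_univariate_single_lv(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 1))
        y = 2.5 * X[:, 0] + 1.0
        model = fit_pls(X, y, 1)
        assert np.allclose(predict(model, X).ravel(), y, atol=1e-8)

    def test_full_rank_equals_ols(self):
        """At n_lv = rank(X), PLS predictions coincide with the normal-
        equations least-squares fit."""
        X, Y = random_xy(seed=4, n=25, p=5, m=2, noise=0.3)
        model = fit_pls(X, Y, 5)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
        ols_fitted = Xc @ beta + Y.mean(axis=0)
        assert np.allclose(predict(model, X), ols_fitted, atol=1e-6)

    def test_pls1_first_weight_proportional_to_xty(self):
        X, y = random_xy(seed=5, n=18, p=7)
        model = fit_pls(X, y, 2)
        Xc = X - X.mean(axis=0)
        yc = (y - y.mean()).ravel()
        direction = Xc.T @ yc
        direction /= np.linalg.norm(direction)
        w1 = model.weights[:, 0]
        assert np.allclose(np.abs(w1 @ direction), 1.0, atol=1e-10)

    def test_scores_orthogonal_and_b_reproduces_training_fit(self):
        X, Y = random_xy(seed=6, n=30, p=8, m=3, noise=0.2)
        model = fit_pls(X, Y, 4)
        TtT = model.scores.T @ model.scores
        assert np.allclose(TtT - np.diag(np.diag(TtT)), 0.0, atol=1e-8)
        Xp = model.preprocess_x(X)
        assert np.allclose(
            Xp @ model.B, model.scores @ model.y_loadings.T, atol=1e-10
        )

    def test_deflation_strictly_shrinks_x_residual(self):
        X, Y = random_xy(seed=7, n=20, p=6, m=2, noise=0.5)
        norms = []
        Xc = X - X.mean(axis=0)
        resid = Xc.copy()
        model = fit_pls(X, Y, 4)
        for a in range(4):
            t = model.scores[:, [a]]
            resid = resid - t @ model.x_loadings[:, [a]].T
            norms.append(np.linalg.norm(resid))
        assert all(b < a for a, b in zip([np.linalg.norm(Xc)] + norms, norms))

    def test_row_permutation_equivariance(self):
        X, Y = random_xy(seed=8, n=15, p=4)
        model = fit_pls(X, Y, 3)
        perm = np.random.default_rng(9).permutation(15)
        permuted = fit_pls(X[perm], Y[perm], 3)
        assert np.allclose(permuted.scores, model.scores[perm], atol=1e-8)
        assert np.allclose(permuted.B, model.B, atol=1e-10)

    def test_excessive_lv_rejected(self):
        X = np.random.default_rng(10).normal(size=(5, 3))
        y = X @ np.ones(3)
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, 5)

    def test_agrees_with_sklearn_predictions(self):
        """Independent route: scikit-learn's PLSRegression on the same data
        produces the same predictions."""
        from sklearn.cross_decomposition import PLSRegression

        X, Y = random_xy(seed=11, n=24, p=7, m=2, noise=0.4)
        for n_lv in (1, 3, 5):
            ours = predict(fit_pls(X, Y, n_lv), X)
            theirs = (
                PLSRegression(n_components=n_lv, scale=False, tol=1e-12, max_iter=5000)
                .fit(X, Y)
                .predict(X)
            )
            # inner-loop stopping rules differ slightly between the two
            assert np.allclose(ours, theirs, atol=1e-5), n_lv


class TestPredict:
    def test_training_predictions_reproduced(self):
        X, Y = random_xy(seed=12)
        model = fit_pls(X, Y, 3)
        again = predict(model, X)
        assert np.allclose(again, predict(model, X), atol=0)

    def test_duplicated_row_duplicates_prediction(self):
        X, Y = random_xy(seed=13)
        model = fit_pls(X, Y, 2)
        pred = predict(model, np.vstack([X[0], X[0]]))
        assert np.allclose(pred[0], pred[1], atol=0)

    def test_two_prediction_paths_agree(self):
        """Coefficient-matrix prediction equals explicit score projection
        t_a = X w_a* per component."""
        X, Y = random_xy(seed=14, n=20, p=6, m=2)
        model = fit_pls(X, Y, 3)
        Xp = model.preprocess_x(X)
        W, P, Q = model.weights, model.x_loadings, model.y_loadings
        Wstar = W @ np.linalg.inv(P.T @ W)
        scores = Xp @ Wstar
        via_scores = scores @ Q.T * model.y_div + model.y_mean
        assert np.allclose(via_scores, predict(model, X), atol=1e-10)

    def test_grid_mismatch_rejected(self):
        X, Y = random_xy(seed=15)
        model = fit_pls(X, Y, 2)
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, X[:, :3])


class TestVenetianBlinds:
    def test_fold_assignment_is_index_modulo(self):
        folds = venetian_blinds_folds(7, 3)
        assert [f.tolist() for f in folds] == [[0, 3, 6], [1, 4], [2, 5]]

    def test_noiseless_rank2_system_prefers_two_lvs(self):
        rng = np.random.default_rng(16)
        T = rng.normal(size=(24, 2))
        X = T @ rng.normal(size=(2, 8))
        y = T @ np.array([1.0, -2.0])
        cv = venetian_blinds_cv(X, y, max_lv=2, n_splits=4)
        assert cv.rmsecv[1] < 1e-8
        assert cv.rmsecv[1] < cv.rmsecv[0]
        assert cv.n_lv == 2

    def test_n_splits_equal_n_is_leave_one_out(self):
        """Explicit LOO loop oracle."""
        X, y = random_xy(seed=17, n=12, p=4, noise=0.3)
        cv = venetian_blinds_cv(X, y, max_lv=3, n_splits=12)
        loo_pred = np.empty((3, 12, 1))
        for i in range(12):
            mask = np.arange(12) != i
            model = fit_pls(X[mask], y[mask], 3)
            for a in range(1, 4):
                loo_pred[a - 1, i] = predict(model, X[[i]], n_lv=a)
        loo_rmse = np.sqrt(np.mean((loo_pred - y[None]) ** 2, axis=(1, 2)))
        assert np.allclose(cv.rmsecv, loo_rmse, atol=1e-10)

    def test_preprocessing_states_never_see_held_out_rows(self):
        """The model predicting fold 0 is fitted (preprocessing included) on
        the other folds only: corrupting fold-0 rows changes neither that
        model nor, therefore, its predictions of any input."""
        X, y = random_xy(seed=18, n=20, p=5, noise=0.2)
        fold0 = np.arange(20) % 4 == 0
        X2, y2 = X.copy(), y.copy()
        X2[fold0] += 1e3
        y2[fold0] -= 1e3
        cv2 = venetian_blinds_cv(X2, y2, max_lv=2, n_splits=4)
        # oracle: fit manually on the untouched training folds, predict the
        # corrupted fold-0 rows
        for a in (1, 2):
            model = fit_pls(X[~fold0], y[~fold0], a)
            expected = predict(model, X2[fold0])
            assert np.allclose(cv2.cv_predictions[a - 1, fold0], expected, atol=1e-9)


class TestSelectNLV:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ((0.9, 0.5, 0.52), 2),
            ((0.5, 0.499, 0.498), 1),  # parsimony: all within 2% of minimum
            ((0.9, 0.7, 0.5), 3),  # strictly decreasing -> max_lv
        ],
    )
    def test_parsimony_rule(self, curve, expected):
        cv = CVResult(
            rmsecv=np.asarray(curve), explained_x=np.zeros(3),
            explained_y=np.zeros(3), n_lv=1, split="",
        )
        assert select_n_lv(cv) == expected


class TestPLSDA:
    def separated_classes(self, seed=19, n_per=8, spread=0.05):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0, 0, 0], [4, 0, 2, 0], [0, 4, 0, 2]], dtype=float)
        X = np.vstack([
            c + spread * rng.normal(size=(n_per, 4)) for c in centers
        ])
        labels = [lab for lab in ("light", "medium", "dark") for _ in range(n_per)]
        return X, labels

    def test_well_separated_classes_classified_perfectly(self):
        X, labels = self.separated_classes()
        model, cv = plsda_fit(X, labels, max_lv=3, n_splits=4)
        assert cv.misclassification[cv.n_lv - 1] == 0.0

    def test_shuffled_labels_near_chance(self):
        X, labels = self.separated_classes(n_per=12)
        rng = np.random.default_rng(20)
        accs = []
        for _ in range(10):
            perm = list(rng.permutation(labels))
            _, cv = plsda_fit(X, perm, max_lv=2, n_splits=4)
            accs.append(1.0 - cv.misclassification[cv.n_lv - 1])
        assert abs(np.mean(accs) - 1 / 3) < 0.15

    def test_identical_samples_with_different_labels_cannot_both_be_right(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(8, 3))
        X[1] = X[0]
        labels = ["a", "b", "a", "b", "a", "b", "a", "b"]
        model, cv = plsda_fit(X, labels, max_lv=2, n_splits=2)
        membership = predict(model, X)
        assigned, _ = plsda_assign(membership, model.classes)
        errors = np.mean(assigned != np.asarray(labels))
        assert errors >= 1 / len(X)

    def test_single_member_class_rejected(self):
        X = np.random.default_rng(22).normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            plsda_fit(X, ["a", "a", "a", "a", "b"], max_lv=2, n_splits=2)


class TestAssignment:
    def test_argmax_assignment(self):
        labels, ties = plsda_assign(
            np.array([[0.9, 0.3, -0.1]]), ["light", "medium", "dark"]
        )
        assert labels[0] == "light" and not ties[0]

    def test_exact_tie_goes_to_first_class_and_is_flagged(self):
        labels, ties = plsda_assign(
            np.array([[0.5, 0.5, 0.0]]), ["light", "medium", "dark"]
        )
        assert labels[0] == "light" and ties[0]

    def test_invariant_to_row_constant_shift(self):
        rng = np.random.default_rng(23)
        pred = rng.normal(size=(10, 3))
        shifted = pred + rng.normal(size=(10, 1))
        a1, _ = plsda_assign(pred, ["a", "b", "c"])
        a2, _ = plsda_assign(shifted, ["a", "b", "c"])
        assert (a1 == a2).all()


class TestClassificationMetrics:
    def test_perfect_assignment(self):
        labels = ["light"] * 3 + ["medium"] * 3 + ["dark"] * 3
        m = classification_metrics(labels, labels, one_hot(labels, sorted(set(labels))))
        assert m.accuracy == 1.0
        assert m.classification_error == 0.0
        assert (m.sensitivity == 1.0).all() and (m.specificity == 1.0).all()
        assert m.r2 == pytest.approx(1.0)

    def test_hand_computed_confusion(self):
        """One-vs-rest counts (TP=8, FN=1, FP=2, TN=9): sensitivity 8/9,
        specificity 9/11."""
        true = ["a"] * 9 + ["b"] * 11
        assigned = ["a"] * 8 + ["b"] + ["a"] * 2 + ["b"] * 9
        m = classification_metrics(true, assigned)
        assert m.sensitivity["a"] == pytest.approx(8 / 9)
        assert m.specificity["a"] == pytest.approx(9 / 11)

    def test_matches_exhaustive_recount(self):
        rng = np.random.default_rng(24)
        classes = ["a", "b", "c"]
        true = rng.choice(classes, 40)
        assigned = rng.choice(classes, 40)
        m = classification_metrics(true, assigned, classes=classes)
        for c in classes:
            tp = sum(t == c and a == c for t, a in zip(true, assigned))
            fn = sum(t == c and a != c for t, a in zip(true, assigned))
            fp = sum(t != c and a == c for t, a in zip(true, assigned))
            tn = 40 - tp - fn - fp
            assert m.sensitivity[c] == pytest.approx(tp / (tp + fn))
            assert m.specificity[c] == pytest.approx(tn / (tn + fp))
        assert m.confusion.to_numpy().sum() == 40

    def test_disjoint_label_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            classification_metrics(["a", "a"], ["b", "b"])
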