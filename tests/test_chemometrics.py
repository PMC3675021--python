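"""NIPALS PCA / PLS1 / OPLS against independent linear-algebra oracles."""

import numpy as np
import pytest
import scipy.stats as st

from metabopls.chemometrics import (
    autofit_components,
    cross_validated_q2,
    fit_opls,
    fit_pca,
    fit_pls,
    hotelling_t2,
    predict_opls,
    predict_pls,
    q2_score,
    stratified_folds,
)
from tests.conftest import two_class_gaussian


def svd_pca_oracle(X, A):
    """Reference PCA via SVD with the same sign convention."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    T = U[:, :A] * s[:A]
    P = Vt[:A].T
    for a in range(A):
        j = np.argmax(np.abs(P[:, a]))
        if P[j, a] < 0:
            P[:, a] *= -1
            T[:, a] *= -1
    return T, P, s[:A] ** 2 / (s**2).sum() * ((s**2).sum() / (X**2).sum())


class TestPCA:
    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 60))
        X -= X.mean(axis=0)
        model = fit_pca(X, 5)
        T, P, expl = svd_pca_oracle(X, 5)
        assert np.allclose(model.scores, T, atol=1e-8)
        assert np.allclose(model.loadings, P, atol=1e-8)
        assert np.allclose(model.explained_fraction, expl[:5], atol=1e-10)

    def test_loadings_orthonormal_scores_orthogonal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 8))
        X -= X.mean(axis=0)
        m = fit_pca(X, 4)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-8)
        G = m.scores.T @ m.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        assert np.all(np.diff(m.explained_fraction) <= 1e-10)

    def test_collinear_points_single_component(self):
        X = np.array([[-2.0, -1.0], [0.0, 0.0], [2.0, 1.0]])
        m = fit_pca(X, 1)
        assert m.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_r2x_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        X -= X.mean(axis=0)
        m = fit_pca(X, 6)
        assert m.cumulative_r2x[-1] == pytest.approx(1.0, abs=1e-9)

    def test_invalid_component_counts(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(5, 3)), 0)
        with pytest.raises(ValueError, match="exceeds"):
            fit_pca(np.random.default_rng(0).normal(size=(5, 3)), 5)


class TestHotelling:
    def test_limit_matches_f_quantile_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 10))
        X -= X.mean(axis=0)
        m = fit_pca(X, 2)
        _, limit, _ = hotelling_t2(m, 0.05)
        expected = (2 * 19 * 21) / (20 * 18) * st.f.ppf(0.95, 2, 18)
        assert limit == pytest.approx(expected, rel=1e-12)
        assert limit == pytest.approx(7.88, abs=0.01)

    def test_extreme_point_flagged(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(19, 3)) * 0.1, [10.0, 10.0, 10.0]])
        X -= X.mean(axis=0)
        m = fit_pca(X, 1)
        _, _, flags = hotelling_t2(m, 0.05)
        assert flags[-1]
        assert flags.sum() == 1

    def test_alpha_one_flags_everything(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        X -= X.mean(axis=0)
        m = fit_pca(X, 2)
        _, limit, flags = hotelling_t2(m, 1.0 - 1e-12)
        assert limit == pytest.approx(0.0, abs=1e-6)
        assert flags.all()


class TestPLS:
    def test_perfect_column_gives_r2y_one(self):
        y = np.repeat([1.0, -1.0], 6)
        X = np.zeros((12, 4))
        X[:, 1] = y
        m = fit_pls(X, y, 1)
        assert m.r2y == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_equals_ols_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 5))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], 6)
        m = fit_pls(X, y, 5)
        fitted = predict_pls(m, X)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        ols_fitted = X @ beta + y.mean()
        assert np.allclose(fitted, ols_fitted, atol=1e-8)

    def test_scores_orthogonal_weights_unit_norm(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 30))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], 10)
        m = fit_pls(X, y, 4)
        G = m.scores.T @ m.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        assert np.allclose(np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-12)

    def test_r2y_non_decreasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(16, 10))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], 8)
        r2y = [fit_pls(X, y, a).r2y for a in range(1, 5)]
        assert np.all(np.diff(r2y) >= -1e-12)

    def test_matches_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 40))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], [12, 13])
        m = fit_pls(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(predict_pls(m, X), ref.predict(X).ravel(), atol=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_pls(X, np.ones(6), 1)

    def test_rank_exhaustion_rejected(self):
        y = np.repeat([1.0, -1.0], 3)
        X = np.outer(y, [1.0, 2.0])  # rank 1
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, 2)

    def test_predict_training_and_errors(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(14, 9))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], 7)
        m = fit_pls(X, y, 2)
        yhat = predict_pls(m, X)
        # duplicated row predicts identically
        assert predict_pls(m, X[[3, 3]])[0] == predict_pls(m, X[[3, 3]])[1]
        # training prediction reproduces the fitted values
        fitted = m.scores @ m.y_loadings + m.y_mean
        assert np.allclose(yhat, fitted, atol=1e-9)
        with pytest.raises(ValueError, match="column mismatch"):
            predict_pls(m, X[:, :5])


class TestOPLS:
    def test_zero_ortho_reduces_to_pls1(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(18, 12))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], 9)
        o = fit_opls(X, y, 0)
        p = fit_pls(X, y, 1)
        assert np.allclose(o.t, p.scores[:, 0], atol=1e-10)
        assert np.allclose(o.w, p.weights[:, 0], atol=1e-10)
        assert np.allclose(o.p, p.x_loadings[:, 0], atol=1e-10)

    @pytest.mark.parametrize("n_ortho", [1, 2, 3])
    def test_prediction_equivalence_with_pls(self, n_ortho):
        """Single-y OPLS with a orthogonal components predicts identically
        to PLS with a+1 components."""
        rng = np.random.default_rng(30 + n_ortho)
        X = rng.normal(size=(30, 200))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], 15)
        Xnew = rng.normal(size=(10, 200))
        o = fit_opls(X, y, n_ortho)
        p = fit_pls(X, y, n_ortho + 1)
        assert np.allclose(predict_opls(o, Xnew), predict_pls(p, Xnew), atol=1e-6)

    def test_orthogonality_invariants(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(24, 50))
        X -= X.mean(axis=0)
        y = np.repeat([1.0, -1.0], 12)
        o = fit_opls(X, y, 3)
        assert np.allclose(o.t @ o.T_o, 0.0, atol=1e-8)
        assert np.allclose(o.w @ o.W_o, 0.0, atol=1e-8)
        assert o.r2x_pred + o.r2x_orth <= 1.0 + 1e-12

    def test_n_ortho_too_large_rejected(self):
        y = np.repeat([1.0, -1.0], 4)
        X = np.outer(y, np.ones(5)) + 1e-9  # effectively rank 1
        with pytest.raises(ValueError, match="n_ortho"):
            fit_opls(X - X.mean(axis=0), y, 3)


class TestCrossValidation:
    def test_q2_score_identities(self):
        y = np.repeat([1.0, -1.0], 10)
        assert q2_score(y, y) == pytest.approx(1.0)
        assert q2_score(y, np.full_like(y, y.mean())) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="constant"):
            q2_score(np.ones(5), np.ones(5))

    def test_perfect_feature_gives_q2_one(self):
        y = np.repeat([1.0, -1.0], 10)
        X = np.zeros((20, 5))
        X[:, 0] = y
        q2, yhat = cross_validated_q2(X, y, "pls", 1, k_folds=5, seed=0)
        assert q2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(yhat, y, atol=1e-9)

    def test_strong_separation_q2_high(self):
        """Two Gaussian classes 4 sigma apart give Q2 > 0.8 across seeds."""
        for seed in range(1, 21):
            X, y = two_class_gaussian(n=40, p=10, delta=4.0, seed=seed)
            q2, _ = cross_validated_q2(X, y, "pls", 1, k_folds=10, seed=seed)
            assert q2 > 0.8, f"seed {seed}: Q2={q2:.3f}"

    def test_q2_never_exceeds_r2y(self):
        from metabopls.preprocess import ScaledMatrix

        for seed in range(5):
            X, y = two_class_gaussian(n=30, p=15, delta=1.0, seed=seed)
            for a in (1, 2, 3):
                m = fit_pls(ScaledMatrix.fit(X, "unit_variance").values, y, a)
                q2, _ = cross_validated_q2(X, y, "pls", a, k_folds=10, seed=seed)
                assert q2 <= m.r2y + 1e-9

    def test_folds_stratified_deterministic_and_label_agnostic(self):
        y = np.repeat([1.0, -1.0], [21, 32])
        f1 = stratified_folds(y, 10, seed=4)
        f2 = stratified_folds(y, 10, seed=4)
        assert np.array_equal(f1, f2)
        assert np.array_equal(f1, stratified_folds(-y, 10, seed=4))
        for f in range(10):
            assert np.unique(y[f1 != f]).size == 2  # both classes in training
        counts = np.bincount(f1)
        assert counts.max() - counts.min() <= 2

    def test_too_many_folds_rejected(self):
        y = np.repeat([1.0, -1.0], 3)
        with pytest.raises(ValueError, match="exceeds"):
            stratified_folds(y, 7, seed=0)

    def test_autofit_prefers_informative_component_count(self):
        X, y = two_class_gaussian(n=40, p=10, delta=4.0, seed=2)
        a, q2s = autofit_components(X, y, k_folds=10, seed=2)
        assert 1 <= a <= 5
        # chosen count maximizes Q2 over the accepted components
        assert q2s[a - 1] == max(q2s[:a])
        assert q2s[a - 1] > 0.8
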