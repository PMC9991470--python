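import numpy as np
import pytest

from eggchem.models import (
    LSSVMClassifier,
    LSSVMModel,
    PLSDAClassifier,
    PLSDAModel,
    decode_labels,
    encode_labels,
    lssvm_fit,
    lssvm_predict,
    pca_fit,
    plsda_fit,
    plsda_predict,
    rbf_kernel,
)


class TestLabelCoding:
    def test_roundtrip(self):
        labels = ["free-range", "caged", "free-range"]
        codes = encode_labels(labels)
        assert list(codes) == [1, -1, 1]
        assert list(decode_labels(codes)) == labels

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="organic"):
            encode_labels(["organic"])

    def test_bad_numeric(self):
        with pytest.raises(ValueError, match=r"\+/-1"):
            encode_labels([0, 1])


class TestPCA:
    def test_rank_one_single_component(self):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, -1.0, 0.5])
        m = pca_fit(X)
        assert m.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_hand_covariance_oracle(self):
        # centered 4-point set; oracle = eigendecomposition of the
        # hand-built 2x2 scatter matrix (independent of the SVD path)
        X = np.array([[3.0, 1.0], [-3.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
        C = np.zeros((2, 2))
        for row in X:
            C += np.outer(row, row)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]

        m = pca_fit(X)
        assert np.allclose(m.explained_variance_ratio, evals / evals.sum())
        for k in range(2):
            cos = abs(float(m.loadings[:, k] @ evecs[:, k]))
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_fractions_sum_to_one_and_decrease(self, rng):
        X = rng.standard_normal((30, 7))
        m = pca_fit(X)
        evr = m.explained_variance_ratio
        assert evr.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_loadings_orthonormal(self, rng):
        X = rng.standard_normal((25, 6))
        m = pca_fit(X, n_components=4)
        G = m.loadings.T @ m.loadings
        assert np.allclose(G, np.eye(4), atol=1e-10)

    def test_scores_match_transform(self, rng):
        X = rng.standard_normal((15, 5))
        m = pca_fit(X, n_components=3)
        assert np.allclose(m.scores, m.transform(X), atol=1e-10)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            pca_fit(np.ones((5, 3)))
        with pytest.raises(ValueError, match="n_components"):
            pca_fit(rng.standard_normal((5, 3)), n_components=4)


class TestPLSDA:
    @pytest.mark.parametrize("seed", range(20))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 5))
        y = np.where(rng.standard_normal(20) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        m = plsda_fit(X, y, 5)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(m.coef, b_ols, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.standard_normal((30, 8))
        y = np.where(rng.standard_normal(30) > 0, 1, -1)
        m = plsda_fit(X, y, 4)
        G = m.x_scores.T @ m.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_separable_1d(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        m = plsda_fit(X, y, 1)
        _, pred = plsda_predict(m, X)
        assert np.array_equal(pred, y)

    def test_zero_score_positive_class(self):
        X = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        y = np.array([-1, 1, -1, 1])
        m = plsda_fit(X, y, 1)
        score, pred = plsda_predict(m, np.array([[0.0]]))
        assert score[0] == pytest.approx(0.0, abs=1e-12)
        assert pred[0] == 1

    def test_lv_exceeding_rank_errors(self, rng):
        X = rng.standard_normal((10, 3))
        X = np.hstack([X, X[:, :1]])  # rank 3 in 4 columns
        y = np.where(rng.standard_normal(10) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        with pytest.raises(ValueError, match="rank"):
            plsda_fit(X, y, 4)

    def test_single_class_errors(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError, match="both classes"):
            plsda_fit(X, np.ones(6), 1)

    def test_serialization_roundtrip(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.where(rng.standard_normal(12) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        m = plsda_fit(X, y, 2)
        m2 = PLSDAModel.from_dict(m.to_dict())
        s1, c1 = plsda_predict(m, X)
        s2, c2 = plsda_predict(m2, X)
        assert np.allclose(s1, s2)
        assert np.array_equal(c1, c2)


class TestLSSVM:
    def test_kkt_against_direct_solve(self, rng):
        X = rng.standard_normal((4, 3))
        y = np.array([1, -1, 1, -1])
        m = lssvm_fit(X, y, sigma2=1.0, gamma=10.0)
        # independent dense construction of the 5x5 system
        K = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                K[i, j] = np.exp(-np.sum((X[i] - X[j]) ** 2) / 1.0)
        M = np.zeros((5, 5))
        M[0, 1:] = 1.0
        M[1:, 0] = 1.0
        M[1:, 1:] = K + np.eye(4) / 10.0
        sol = np.linalg.solve(M, np.concatenate(([0.0], y)))
        assert m.bias == pytest.approx(sol[0], abs=1e-10)
        assert np.allclose(m.alpha, sol[1:], atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_kkt_residual_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, 4))
        y = np.where(rng.standard_normal(15) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        m = lssvm_fit(X, y, sigma2=5.0, gamma=2.0)
        K = rbf_kernel(X, X, 5.0)
        M = np.zeros((16, 16))
        M[0, 1:] = 1.0
        M[1:, 0] = 1.0
        M[1:, 1:] = K + np.eye(15) / 2.0
        rhs = np.concatenate(([0.0], y))
        sol = np.concatenate(([m.bias], m.alpha))
        assert np.linalg.norm(M @ sol - rhs) < 1e-8

    def test_alpha_sums_to_zero(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array([1, -1] * 5)
        m = lssvm_fit(X, y, sigma2=2.0, gamma=1.0)
        assert abs(m.alpha.sum()) < 1e-8

    def test_symmetric_data_zero_bias(self, rng):
        Xp = rng.standard_normal((5, 3))
        X = np.vstack([Xp, -Xp])
        y = np.array([1] * 5 + [-1] * 5)
        m = lssvm_fit(X, y, sigma2=1.0, gamma=3.0)
        assert abs(m.bias) < 1e-10

    def test_interpolation_limit(self, rng):
        X = rng.standard_normal((8, 2))
        y = np.array([1, -1] * 4)
        m = lssvm_fit(X, y, sigma2=1.0, gamma=1e8)
        f, _ = lssvm_predict(m, X)
        assert np.allclose(f, y, atol=1e-5)

    def test_reorder_invariance(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array([1, -1] * 6)
        perm = rng.permutation(12)
        m1 = lssvm_fit(X, y, sigma2=3.0, gamma=2.0)
        m2 = lssvm_fit(X[perm], y[perm], sigma2=3.0, gamma=2.0)
        Xnew = rng.standard_normal((5, 3))
        f1, _ = lssvm_predict(m1, Xnew)
        f2, _ = lssvm_predict(m2, Xnew)
        assert np.allclose(f1, f2, atol=1e-8)

    def test_invalid_params(self, rng):
        X = rng.standard_normal((6, 2))
        y = np.array([1, -1] * 3)
        with pytest.raises(ValueError):
            lssvm_fit(X, y, sigma2=0.0, gamma=1.0)
        with pytest.raises(ValueError):
            lssvm_fit(X, y, sigma2=1.0, gamma=-1.0)

    def test_serialization_roundtrip(self, rng):
        X = rng.standard_normal((8, 3))
        y = np.array([1, -1] * 4)
        m = lssvm_fit(X, y, sigma2=2.0, gamma=4.0)
        m2 = LSSVMModel.from_dict(m.to_dict())
        f1, c1 = lssvm_predict(m, X)
        f2, c2 = lssvm_predict(m2, X)
        assert np.allclose(f1, f2)
        assert np.array_equal(c1, c2)


class TestClassifierWrappers:
    @pytest.mark.parametrize("cls,kwargs", [
        (PLSDAClassifier, {"n_components": 2}),
        (LSSVMClassifier, {"sigma2": 10.0, "gamma": 5.0}),
    ])
    def test_fit_predict_separable(self, cls, kwargs, rng):
        X = np.vstack([
            rng.standard_normal((20, 3)) + [5, 0, 0],
            rng.standard_normal((20, 3)) - [5, 0, 0],
        ])
        y = np.array([1] * 20 + [-1] * 20)
        clf = cls(**kwargs).fit(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_scaler_fit_on_training_only(self, rng):
        X = rng.standard_normal((30, 4)) * 7 + 3
        y = np.array([1, -1] * 15)
        clf = PLSDAClassifier(n_components=2).fit(X, y)
        assert np.allclose(clf.center_, X.mean(axis=0))
        assert np.allclose(clf.scale_, X.std(axis=0, ddof=1))
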