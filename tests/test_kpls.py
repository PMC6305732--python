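import numpy as np
import pytest

from focmts import kpls


def _reference_kpls_predict(X, y, X_new, width, n_components):
    """Independent dual-form KPLS implementation used as an oracle.

    Written directly from the published dual algorithm: score extraction by
    power-style iteration on the centered kernel, deflation of K by the
    projector (I - t t'), and the closed-form dual coefficients
    B = U (T' K U)^-1 T' y.  No code shared with the implementation under
    test beyond numpy.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(X)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-sq / (2 * width ** 2))
    H = np.eye(n) - np.ones((n, n)) / n
    Kc = H @ K @ H
    yc = (y - y.mean())[:, None]
    Kd, Yd = Kc.copy(), yc.copy()
    T, U = [], []
    for _ in range(n_components):
        u = Yd[:, 0]
        t = Kd @ u
        t = t / np.linalg.norm(t)
        c = Yd.T @ t
        T.append(t)
        U.append(u)
        P = np.eye(n) - np.outer(t, t)
        Kd = P @ Kd @ P
        Yd = Yd - np.outer(t, c)
    T = np.column_stack(T)
    U = np.column_stack(U)
    B = U @ np.linalg.solve(T.T @ Kc @ U, T.T @ yc)
    sq_new = ((np.asarray(X_new, float)[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    Kt = np.exp(-sq_new / (2 * width ** 2))
    nt = len(Kt)
    Ktc = (Kt - np.ones((nt, n)) @ K / n) @ H
    return (Ktc @ B)[:, 0] + y.mean()


class TestGaussianKernel:
    def test_unit_diagonal(self):
        A = np.random.default_rng(0).standard_normal((5, 3))
        K = kpls.gaussian_kernel_matrix(A, A, width=1.3)
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)

    def test_hand_arithmetic(self):
        K = kpls.gaussian_kernel_matrix([[0.0, 0.0]], [[3.0, 4.0]], width=5.0)
        assert K[0, 0] == pytest.approx(np.exp(-0.5))

    def test_distant_points_vanish(self):
        K = kpls.gaussian_kernel_matrix([[0.0]], [[1e4]], width=1.0)
        assert K[0, 0] == 0.0

    def test_positive_semidefinite(self):
        A = np.random.default_rng(1).standard_normal((20, 4))
        K = kpls.gaussian_kernel_matrix(A, A, width=2.0)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_invalid_width_or_shape(self):
        with pytest.raises(ValueError):
            kpls.gaussian_kernel_matrix([[0.0]], [[1.0]], width=0.0)
        with pytest.raises(ValueError):
            kpls.gaussian_kernel_matrix([[0.0, 1.0]], [[1.0]], width=1.0)


class TestFitKpls:
    @pytest.mark.parametrize("n, m, seed", [(12, 3, 0), (25, 4, 1), (9, 2, 2)])
    def test_linear_kernel_full_components_matches_ols(self, n, m, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, m))
        y = X @ rng.standard_normal(m) + rng.standard_normal(n) * 0.2
        model = kpls.fit_kpls(X, y, n_components=m, kernel="linear")
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        design = np.column_stack([np.ones(n), Z])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(model.fitted, design @ beta, atol=1e-6)

    def test_constant_response_predicts_constant(self):
        X = np.random.default_rng(3).standard_normal((10, 2))
        model = kpls.fit_kpls(X, np.full(10, 4.2), n_components=3)
        np.testing.assert_allclose(model.fitted, 4.2)
        np.testing.assert_allclose(model.predict(X * 2), 4.2)

    def test_training_predictions_reproduce_fitted(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((18, 3))
        y = np.sin(X[:, 0]) + rng.standard_normal(18) * 0.1
        model = kpls.fit_kpls(X, y, n_components=4)
        np.testing.assert_allclose(model.predict(X), model.fitted, atol=1e-8)

    def test_far_point_predicts_response_mean(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 2))
        y = X[:, 0] + rng.standard_normal(15) * 0.1
        model = kpls.fit_kpls(X, y, n_components=2, width=1.0)
        far = model.predict(np.array([[500.0, -500.0]]))
        assert far[0] == pytest.approx(y.mean(), abs=0.05)

    def test_duplication_invariance_of_dual_core(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((15, 3))
        y = np.sin(Z[:, 0]) + rng.standard_normal(15) * 0.1
        Znew = rng.standard_normal((5, 3))

        def core_predict(Zt, yt):
            K = kpls.gaussian_kernel_matrix(Zt, Zt, 2.0)
            Kc = kpls._center_train_kernel(K)
            yc = yt - yt.mean()
            T, U = kpls._extract_components(Kc, yc, 3)
            d = kpls._dual_coefficients(Kc, yc, T, U)
            Kt = kpls.gaussian_kernel_matrix(Znew, Zt, 2.0)
            return kpls._center_test_kernel(Kt, K) @ d + yt.mean()

        single = core_predict(Z, y)
        doubled = core_predict(np.vstack([Z, Z]), np.concatenate([y, y]))
        np.testing.assert_allclose(single, doubled, atol=1e-10)

    def test_monotone_fitted_r2_in_components(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 4))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + rng.standard_normal(30) * 0.2
        prev = -np.inf
        for c in range(1, 8):
            model = kpls.fit_kpls(X, y, n_components=c, width=2.0)
            r2 = kpls.fitted_r2(model, y)
            assert r2 >= prev - 1e-10
            prev = r2

    def test_response_translation_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((16, 3))
        y = X[:, 0] ** 2 + rng.standard_normal(16) * 0.1
        Xnew = rng.standard_normal((4, 3))
        m1 = kpls.fit_kpls(X, y, n_components=2, width=2.0)
        m2 = kpls.fit_kpls(X, y + 1000.0, n_components=2, width=2.0)
        np.testing.assert_allclose(m2.predict(Xnew), m1.predict(Xnew) + 1000.0,
                                   atol=1e-7)

    def test_against_independent_dual_form_oracle(self):
        # 6-point worked fixture vs. a second implementation of the algorithm
        X = np.array([[0.0, 1.0], [1.0, 0.5], [2.0, -0.5],
                      [3.0, 0.2], [4.0, 1.5], [5.0, -1.0]])
        y = np.array([0.3, 1.1, 1.9, 2.5, 4.2, 4.8])
        width = 2.0
        for ncomp in (1, 2, 3):
            model = kpls.fit_kpls(X, y, n_components=ncomp, width=width)
            X_new = np.array([[1.5, 0.0], [3.5, 1.0]])
            got = model.predict(X_new)
            want = _reference_kpls_predict(model.X_train, y,
                                           (X_new - model.x_mean) / model.x_std,
                                           width, ncomp)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_components_truncated_with_warning(self):
        X = np.random.default_rng(9).standard_normal((5, 2))
        y = X[:, 0]
        with pytest.warns(UserWarning):
            model = kpls.fit_kpls(X, y, n_components=10)
        assert model.n_components <= 4

    def test_dimension_mismatch_on_predict(self):
        X = np.random.default_rng(10).standard_normal((8, 3))
        model = kpls.fit_kpls(X, X[:, 0], n_components=1)
        with pytest.raises(ValueError):
            model.predict(np.ones((2, 5)))


class TestLooR2:
    def test_exact_linear_signal(self):
        x = np.linspace(-2, 2, 10)[:, None]
        y = 2.0 * x[:, 0]
        r2 = kpls.loo_r2(x, y, n_components=1, kernel="linear")
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_hand_unrolled_four_fold(self):
        X = np.array([[0.0, 1.0], [1.0, -1.0], [2.0, 0.5], [3.0, 0.0]])
        y = np.array([1.0, 2.0, 2.5, 4.0])
        r2 = kpls.loo_r2(X, y, n_components=1, width=1.5)
        preds = np.empty(4)
        for i in range(4):
            mask = np.arange(4) != i
            model = kpls.fit_kpls(X[mask], y[mask], n_components=1, width=1.5)
            preds[i] = model.predict(X[i:i + 1])[0]
        expected = 1.0 - ((y - preds) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(expected, abs=1e-12)

    def test_fitted_always_at_least_cv(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((25, 3))
            y = X[:, 0] + 0.5 * np.sin(X[:, 1]) + r.standard_normal(25) * 0.4
            comps = 2
            model = kpls.fit_kpls(X, y, n_components=comps)
            fit = kpls.fitted_r2(model, y)
            cv = kpls.loo_r2(X, y, n_components=comps)
            assert fit >= cv

    def test_errors(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="variance"):
            kpls.loo_r2(np.random.default_rng(0).standard_normal((4, 1)),
                        np.ones(4))
        with pytest.raises(ValueError):
            kpls.loo_r2(np.zeros((2, 1)), np.array([0.0, 1.0]))


class TestChooseComponents:
    def test_selects_within_range_and_helps(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((40, 3))
        y = np.sin(X[:, 0]) + X[:, 1] + rng.standard_normal(40) * 0.2
        c = kpls.choose_components(X, y)
        assert 1 <= c <= 10
        r2 = kpls.loo_r2(X, y, n_components=c)
        assert r2 > 0.3
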