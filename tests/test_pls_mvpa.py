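"""PLS core: NIPALS extraction, MCCV selection, target projection, CIs.

Two independent oracles check the fitted models: the Krylov-subspace
characterisation of PLS1 (the A-component regression vector is the least-
squares solution restricted to span{X'y, (X'X)X'y, ...}) and
scikit-learn's cross_decomposition implementation.
"""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from actipls import (
    fit_pls, predict, mccv_select, target_projection,
    mv_correlation_ci, explained_variance,
)


def krylov_pls_coef(X, y, A):
    """Independent PLS1 oracle via its Krylov-space characterisation."""
    s = X.T @ y
    G = X.T @ X
    K = np.empty((X.shape[1], A))
    v = s.copy()
    for a in range(A):
        K[:, a] = v
        v = G @ v
    Q, _ = np.linalg.qr(K)
    coef, *_ = np.linalg.lstsq(X @ Q, y, rcond=None)
    return Q @ coef


def centered_fixture(rng, n=60, p=23):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n)
    return X - X.mean(0), y - y.mean()


class TestFitPLS:
    def test_full_component_model_equals_ols(self, rng):
        for _ in range(10):
            X, y = centered_fixture(rng, n=50, p=8)
            b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            m = fit_pls(X, y, A=8)
            np.testing.assert_allclose(m.b, b_ols, atol=1e-8)

    def test_single_predictor_equals_simple_regression(self, rng):
        X, y = centered_fixture(rng, n=40, p=1)
        m = fit_pls(X, y, A=1)
        slope = float(X[:, 0] @ y / (X[:, 0] @ X[:, 0]))
        assert m.b[0] == pytest.approx(slope, abs=1e-12)

    def test_predictions_match_krylov_oracle(self, rng):
        for _ in range(5):
            X, y = centered_fixture(rng)
            for A in (1, 2, 3, 4):
                m = fit_pls(X, y, A)
                np.testing.assert_allclose(
                    predict(m, X), X @ krylov_pls_coef(X, y, A), atol=1e-8)

    def test_predictions_match_sklearn(self, rng):
        for _ in range(5):
            X, y = centered_fixture(rng)
            for A in (1, 3, 5):
                m = fit_pls(X, y, A)
                sk = PLSRegression(n_components=A, scale=False).fit(X, y)
                np.testing.assert_allclose(
                    predict(m, X), sk.predict(X).ravel(), atol=1e-8)

    def test_score_orthogonality(self, rng):
        X, y = centered_fixture(rng)
        m = fit_pls(X, y, 6)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * len(y)

    def test_r2_cal_nondecreasing_in_components(self, rng):
        X, y = centered_fixture(rng)
        sst = float(y @ y)
        last = -np.inf
        for A in range(1, 8):
            resid = y - predict(fit_pls(X, y, A), X)
            r2 = 1 - float(resid @ resid) / sst
            assert r2 >= last - 1e-12
            last = r2

    def test_invalid_component_count_rejected(self, rng):
        X, y = centered_fixture(rng, n=20, p=5)
        with pytest.raises(ValueError):
            fit_pls(X, y, 0)
        with pytest.raises(ValueError):
            fit_pls(X, y, 25)

    def test_early_stop_when_y_orthogonal(self):
        X = np.diag([1.0, 1.0, 1.0]) - 1 / 3
        y = np.zeros(3)
        with pytest.raises(ValueError):
            fit_pls(X, y, 2)


class TestPredict:
    def test_column_mismatch_rejected(self, rng):
        X, y = centered_fixture(rng, n=30, p=5)
        m = fit_pls(X, y, 2)
        with pytest.raises(ValueError):
            predict(m, np.zeros((4, 6)))

    def test_zero_matrix_predicts_zero(self, rng):
        X, y = centered_fixture(rng, n=30, p=5)
        m = fit_pls(X, y, 2)
        np.testing.assert_allclose(predict(m, np.zeros((4, 5))), 0.0)


class TestMCCV:
    def test_pure_noise_selects_zero_components(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 23))
        y = rng.normal(size=400)
        X, y = X - X.mean(0), y - y.mean()
        assert mccv_select(X, y, seed=0).selected_A == 0

    def test_noiseless_one_dim_signal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 10))
        X -= X.mean(0)
        y = X @ np.r_[1.0, np.zeros(9)]
        res = mccv_select(X, y, seed=1)
        assert res.selected_A >= 1
        assert res.median_rmsep[res.selected_A] < 1e-8

    def test_deterministic_given_seed(self, rng):
        X, y = centered_fixture(rng, n=80)
        r1 = mccv_select(X, y, reps=20, seed=5)
        r2 = mccv_select(X, y, reps=20, seed=5)
        np.testing.assert_array_equal(r1.rmsep, r2.rmsep)
        assert r1.selected_A == r2.selected_A

    def test_rmsep_shape_and_nonnegativity(self, rng):
        X, y = centered_fixture(rng, n=80)
        res = mccv_select(X, y, reps=20, A_max=5, seed=2)
        assert res.rmsep.shape == (20, 6)
        assert (res.rmsep >= 0).all()

    def test_tiny_sample_rejected(self, rng):
        X, y = centered_fixture(rng, n=8, p=3)
        with pytest.raises(ValueError):
            mccv_select(X, y, seed=0)


class TestTargetProjection:
    def test_single_component_r_equals_correlation_loadings(self, rng):
        X, y = centered_fixture(rng)
        m = fit_pls(X, y, 1)
        t_tp, r = target_projection(m, X)
        t1 = m.T[:, 0]
        # t_tp collinear with the first score
        c = np.corrcoef(t_tp, t1)[0, 1]
        assert abs(abs(c) - 1) < 1e-10
        loadings = [np.corrcoef(X[:, k], t1)[0, 1] for k in range(X.shape[1])]
        np.testing.assert_allclose(r, np.sign(c) * np.array(loadings), atol=1e-10)

    def test_collinear_column_attains_bound(self, rng):
        X, y = centered_fixture(rng, n=50, p=4)
        m = fit_pls(X, y, 2)
        t_tp, _ = target_projection(m, X)
        X2 = np.column_stack([X, t_tp - t_tp.mean()])
        m2 = fit_pls(X2, y, 2)
        _, r2 = target_projection(m2, X2)
        assert np.abs(r2).max() <= 1.0 + 1e-12

    def test_r_equals_correlation_with_predictions(self, rng):
        X, y = centered_fixture(rng)
        m = fit_pls(X, y, 3)
        _, r = target_projection(m, X)
        yhat = predict(m, X)
        alt = [np.corrcoef(X[:, k], yhat)[0, 1] for k in range(X.shape[1])]
        np.testing.assert_allclose(r, alt, atol=1e-10)


class TestCIsAndR2:
    def test_noiseless_signal_all_cis_exclude_zero(self):
        rng = np.random.default_rng(3)
        lat = rng.normal(size=(300, 1))
        X = lat + 0.1 * rng.normal(size=(300, 6))
        X -= X.mean(0)
        y = X @ np.ones(6)
        y -= y.mean()
        res = mccv_select(X, y, reps=50, seed=3)
        m = fit_pls(X, y, max(res.selected_A, 1))
        lo, hi, _ = mv_correlation_ci(X, y, m.A, res.splits, b_full=m.b)
        assert (lo > 0).all()
        assert (hi - lo < 0.05).all()

    def test_explained_variance_noiseless(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 5))
        X -= X.mean(0)
        y = X @ rng.normal(size=5)
        y = (y - y.mean()) / y.std(ddof=1)
        res = mccv_select(X, y, reps=40, seed=4)
        m = fit_pls(X, y, res.selected_A)
        r2c, r2v = explained_variance(m, X, y, res)
        assert r2c == pytest.approx(1.0, abs=1e-10)
        assert r2v == pytest.approx(1.0, abs=1e-6)

    def test_no_model_has_no_r2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        X, y = X - X.mean(0), (y - y.mean()) / y.std(ddof=1)
        res = mccv_select(X, y, seed=6)
        if res.selected_A == 0:
            m = fit_pls(X, y, 1)
            with pytest.raises(ValueError):
                explained_variance(m, X, y, res)
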