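import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from nirimpurity.chemometric_models import (
    DEFAULT_N_COMPONENTS,
    fit_lssvm,
    fit_plsr,
    fit_svr,
    load_model,
    predict,
    save_model,
)


class TestPlsr:
    def test_exact_linear_full_rank(self, rng):
        X = rng.normal(size=(20, 5))
        beta = rng.normal(size=5)
        y = X @ beta + 1.3
        model = fit_plsr(X, y, 5)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_ols_oracle_at_full_rank(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, 4)
        # normal-equations OLS on centered data
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        np.testing.assert_allclose(model.coef, beta_ols, atol=1e-6)

    def test_default_components(self):
        assert DEFAULT_N_COMPONENTS == 4

    def test_one_component_univariate_is_simple_regression(self, rng):
        x = rng.normal(size=30)
        y = 2.5 * x + 1.0 + rng.normal(0, 0.1, size=30)
        model = fit_plsr(x[:, None], y, 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef[0] == pytest.approx(slope, abs=1e-10)

    def test_excess_components_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="n_components"):
            fit_plsr(X, rng.normal(size=6), 6)


class TestSvr:
    def test_constant_target(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.full(12, 4.2)
        model = fit_svr(X, y, C=1.0, gamma=0.5, epsilon=0.01)
        np.testing.assert_allclose(model.predict(X), 4.2, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_qp_oracle_objective(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        C, gamma, eps = 2.0, 0.7, 0.05
        model = fit_svr(X, y, C=C, gamma=gamma, epsilon=eps)

        # brute-force QP on beta_i = alpha_i - alpha_i^* with |beta_i| <= C,
        # sum beta = 0, objective -1/2 b'Kb - eps*sum|b| + y'b (maximize)
        Z = (X - model.x_mean) / model.x_scale
        K = np.exp(-gamma * cdist(Z, Z, "sqeuclidean"))

        def neg_obj(b):
            return 0.5 * b @ K @ b + eps * np.sum(np.abs(b)) - y @ b

        best = None
        for trial in range(8):
            b0 = rng.uniform(-C, C, 5)
            b0 -= b0.mean()
            res = minimize(
                neg_obj, b0, method="SLSQP",
                bounds=[(-C, C)] * 5,
                constraints={"type": "eq", "fun": lambda b: np.sum(b)},
                options={"maxiter": 500, "ftol": 1e-12},
            )
            if best is None or res.fun < best:
                best = res.fun
        assert model.dual_objective(y) == pytest.approx(-best, abs=1e-5)

    def test_duplicate_non_support_point_invariance(self, rng):
        # standardization disabled so the duplicated row cannot shift the
        # feature statistics; only the solver's behavior is under test
        X = rng.normal(size=(20, 2))
        y = np.sin(X[:, 0]) + 0.1 * X[:, 1]
        model = fit_svr(X, y, C=10.0, gamma=0.5, epsilon=0.1, standardize=False)
        non_support = sorted(set(range(20)) - set(model.support_idx.tolist()))
        if not non_support:
            pytest.skip("no non-support vectors at these hyperparameters")
        i = non_support[0]
        X2 = np.vstack([X, X[i]])
        y2 = np.append(y, y[i])
        model2 = fit_svr(X2, y2, C=10.0, gamma=0.5, epsilon=0.1, standardize=False)
        grid = rng.normal(size=(15, 2))
        np.testing.assert_allclose(model.predict(grid), model2.predict(grid), atol=1e-6)

    def test_prediction_envelope(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.uniform(-1, 1, size=25)
        model = fit_svr(X, y, C=1.0, gamma=0.3, epsilon=0.05)
        preds = model.predict(X)
        assert np.all(np.abs(preds) <= np.abs(y).max() + 0.05 + 1e-6)

    def test_grid_search_runs(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        model = fit_svr(X, y, C_grid=(0.1, 10.0), gamma_grid=(0.1, 1.0), seed=1)
        assert model.C in (0.1, 10.0) and model.gamma in (0.1, 1.0)

    def test_degenerate_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            fit_svr(rng.normal(size=(10, 2)), rng.normal(size=10), C_grid=())


class TestLssvm:
    def test_single_point(self):
        model = fit_lssvm(np.array([[1.0]]), np.array([3.0]), gamma=1.0, sigma=1.0)
        assert model.bias == pytest.approx(3.0, abs=1e-10)
        assert model.alpha[0] == pytest.approx(0.0, abs=1e-10)
        assert model.predict(np.array([[1.0]]))[0] == pytest.approx(3.0, abs=1e-10)

    def test_kkt_residual_oracle(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        gamma, sigma = 5.0, 1.2
        model = fit_lssvm(X, y, gamma=gamma, sigma=sigma)
        # independently assemble the KKT system and check the residual
        Z = (X - model.x_mean) / model.x_scale
        K = np.exp(-cdist(Z, Z, "sqeuclidean") / (2 * sigma**2))
        A = np.block([
            [np.zeros((1, 1)), np.ones((1, 12))],
            [np.ones((12, 1)), K + np.eye(12) / gamma],
        ])
        sol = np.concatenate([[model.bias], model.alpha])
        rhs = np.concatenate([[0.0], y])
        assert np.max(np.abs(A @ sol - rhs)) < 1e-8

    def test_large_gamma_interpolation(self, rng):
        X = rng.uniform(-1, 1, size=(20, 1))
        y = np.sin(2 * X[:, 0])
        model = fit_lssvm(X, y, gamma=1e6, sigma=1.0)
        resid = model.predict(X) - y
        assert np.sqrt(np.mean(resid**2)) < 1e-3

    def test_training_error_monotone_in_gamma(self, rng):
        X = rng.normal(size=(25, 2))
        y = np.cos(X[:, 0]) + 0.1 * rng.normal(size=25)
        errs = []
        for gamma in (0.1, 1.0, 10.0, 100.0, 1000.0):
            model = fit_lssvm(X, y, gamma=gamma, sigma=1.0)
            errs.append(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        assert all(b <= a + 1e-10 for a, b in zip(errs, errs[1:]))


class TestPredictContract:
    def test_training_predictions_reproducible(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        model = fit_plsr(X, y, 3)
        np.testing.assert_array_equal(predict(model, X), model.predict(X))

    def test_dimension_guard(self, rng):
        X = rng.normal(size=(15, 4))
        model = fit_plsr(X, rng.normal(size=15), 3, feature_indices=(0, 1, 2, 3))
        with pytest.raises(ValueError, match="expected 4 features"):
            predict(model, rng.normal(size=(3, 5)))

    def test_batch_equals_per_sample(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        for model in (
            fit_plsr(X, y, 2),
            fit_svr(X, y, C=1.0, gamma=0.5),
            fit_lssvm(X, y, gamma=10.0, sigma=1.0),
        ):
            Xnew = rng.normal(size=(6, 4))
            batch = predict(model, Xnew)
            singles = np.concatenate([predict(model, row[None, :]) for row in Xnew])
            np.testing.assert_allclose(batch, singles, atol=1e-12)


class TestModelArtifacts:
    @pytest.mark.parametrize("kind", ["plsr", "svr", "lssvm"])
    def test_round_trip(self, kind, rng, tmp_path):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        if kind == "plsr":
            model = fit_plsr(X, y, 2, feature_indices=(0, 1, 2))
        elif kind == "svr":
            model = fit_svr(X, y, C=1.0, gamma=0.5)
        else:
            model = fit_lssvm(X, y, gamma=10.0, sigma=1.0)
        back = load_model(save_model(model, tmp_path / f"{kind}.json"))
        Xnew = rng.normal(size=(5, 3))
        np.testing.assert_allclose(back.predict(Xnew), model.predict(Xnew), atol=1e-12)
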