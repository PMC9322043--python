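"""PLSR/LSSVM learners, CV tooling, metrics and hyperparameter selection."""

import numpy as np
import pytest

from ovaspec import (
    LSSVMRegressor,
    PLSRRegressor,
    compute_metrics,
    fit_lssvm,
    fit_plsr,
    grid_search_lssvm,
    kfold_cv,
    load_model,
    save_model,
    select_n_lv,
)
from ovaspec.regression import _cv_rmse_per_lv, plateau_lv


def _random_problem(rng, n=40, p=8, noise=0.1):
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(0, noise, n)
    return X, y


class TestPLSR:
    def test_single_factor_exact_fit(self):
        """With orthogonal (centered) predictors, y linear in one column is
        captured exactly by the first latent variable."""
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(30, 5))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = 3.0 * X[:, 2] + 1.0
        model = fit_plsr(X, y, n_lv=1)
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_equals_ols_at_full_rank(self):
        rng = np.random.default_rng(1)
        X, y = _random_problem(rng)
        model = fit_plsr(X, y, n_lv=8)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.abs(model.coef_ - b_ols).max() < 1e-6

    def test_matches_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        X, y = _random_problem(rng, n=25, p=10)
        ours = fit_plsr(X, y, n_lv=4)
        theirs = PLSRegression(n_components=4, scale=False).fit(X, y)
        assert np.allclose(ours.coef_, theirs.coef_.ravel(), atol=1e-8)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(3)
        X, y = _random_problem(rng, n=20, p=8)
        model = fit_plsr(X, y, n_lv=3)
        gram = model.x_scores_.T @ model.x_scores_
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_unit_norm_weights(self):
        rng = np.random.default_rng(4)
        X, y = _random_problem(rng)
        model = fit_plsr(X, y, n_lv=5)
        assert np.allclose(np.linalg.norm(model.x_weights_, axis=0), 1.0)

    @pytest.mark.parametrize("h", [0, 9, 40])
    def test_lv_out_of_range(self, h):
        rng = np.random.default_rng(5)
        X, y = _random_problem(rng, n=9, p=8)
        with pytest.raises(ValueError):
            fit_plsr(X, y, n_lv=h)

    def test_rank_deficiency_names_component(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10.0)
        y = X[:, 0].copy()
        with pytest.raises(np.linalg.LinAlgError, match="component 2"):
            fit_plsr(X, y, n_lv=2)


class TestLSSVM:
    def test_single_training_point(self):
        model = fit_lssvm(np.array([[1.0, 2.0]]), np.array([5.0]), gamma=10.0, sigma=1.0)
        assert model.predict([[1.0, 2.0]])[0] == pytest.approx(5.0, abs=1e-8)

    def test_large_gamma_interpolates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        model = fit_lssvm(X, y, gamma=1e8, sigma=2.0)
        assert np.abs(model.predict(X) - y).max() < 1e-4

    def test_kernel_diagonal_is_one(self):
        model = LSSVMRegressor(sigma=0.7)
        K = model._kernel(np.ones((3, 2)), np.ones((3, 2)))
        assert np.allclose(K, 1.0)

    def test_kkt_residual_tiny(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X, y = _random_problem(rng, n=25, p=4)
            model = fit_lssvm(X, y, gamma=rng.uniform(0.1, 100), sigma=rng.uniform(0.5, 5))
            assert model.kkt_residual_ < 1e-8

    def test_kkt_system_against_direct_construction(self):
        """Independent oracle: assemble the KKT system loop-wise and solve."""
        rng = np.random.default_rng(2)
        X, y = _random_problem(rng, n=12, p=3)
        gamma, sigma = 7.0, 1.3
        model = fit_lssvm(X, y, gamma=gamma, sigma=sigma)
        n = len(y)
        z = (y - y.mean()) / y.std()
        A = np.zeros((n + 1, n + 1))
        for i in range(n):
            A[0, i + 1] = A[i + 1, 0] = 1.0
            for j in range(n):
                k = np.exp(-np.sum((X[i] - X[j]) ** 2) / (2 * sigma**2))
                A[i + 1, j + 1] = k + (1.0 / gamma if i == j else 0.0)
        sol = np.linalg.solve(A, np.concatenate([[0.0], z]))
        assert sol[0] == pytest.approx(model.bias_, abs=1e-10)
        assert np.allclose(sol[1:], model.alpha_, atol=1e-10)

    def test_training_rmse_monotone_in_gamma(self):
        rng = np.random.default_rng(3)
        X, y = _random_problem(rng, n=30, p=4, noise=0.5)
        rmses = []
        for g in [0.01, 0.1, 1, 10, 100, 1e4]:
            model = fit_lssvm(X, y, gamma=g, sigma=2.0)
            rmses.append(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            fit_lssvm(np.ones((2, 1)), np.ones(2), gamma=-1.0, sigma=1.0)


class TestCV:
    def test_perfect_linear_data_zero_rmsecv(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        m = kfold_cv(PLSRRegressor(n_components=1), X, y, k=5, seed=0)
        # single-LV PLS is not OLS, so allow the model class a few LVs
        m4 = kfold_cv(PLSRRegressor(n_components=4), X, y, k=5, seed=0)
        assert m4.rmse < 1e-8

    def test_k_equals_n_is_loo(self):
        rng = np.random.default_rng(1)
        X, y = _random_problem(rng, n=12, p=3)
        learner = PLSRRegressor(n_components=2)
        metrics = kfold_cv(learner, X, y, k=12, seed=0)
        preds = np.empty(12)
        for i in range(12):
            tr = np.delete(np.arange(12), i)
            preds[i] = PLSRRegressor(n_components=2).fit(X[tr], y[tr]).predict(X[[i]])[0]
        expected = np.sqrt(np.mean((preds - y) ** 2))
        assert metrics.rmse == pytest.approx(expected, abs=1e-12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X, y = _random_problem(rng, n=30, p=5, noise=1.0)
        a = kfold_cv(PLSRRegressor(n_components=3), X, y, k=5, seed=9)
        b = kfold_cv(PLSRRegressor(n_components=3), X, y, k=5, seed=9)
        assert a == b

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(PLSRRegressor(1), np.ones((3, 2)), np.arange(3.0), k=5)

    def test_truncated_coefficients_match_refit(self):
        rng = np.random.default_rng(3)
        X, y = _random_problem(rng, n=25, p=10, noise=0.5)
        full = fit_plsr(X, y, n_lv=6)
        for h in (1, 3, 5):
            assert np.allclose(full.coefficients_for(h), fit_plsr(X, y, h).coef_, atol=1e-10)


class TestSelectLV:
    def test_plateau_rule_is_argmin_at_zero_tol(self):
        rmse = np.array([5.0, 3.0, 2.0, 1.0, 1.5, 2.0])
        assert plateau_lv(rmse, tol=0.0) == 4

    def test_flat_curve_picks_one(self):
        assert plateau_lv(np.full(8, 2.0), tol=0.0) == 1

    def test_plateau_prefers_parsimony(self):
        rmse = np.array([5.0, 1.01, 1.0, 1.0])
        assert plateau_lv(rmse, tol=0.02) == 2

    def test_on_data_with_known_dimension(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(80, 2))
        loadings = rng.normal(size=(2, 20))
        X = scores @ loadings + rng.normal(0, 0.01, (80, 20))
        y = scores @ np.array([1.0, -1.0]) + rng.normal(0, 0.01, 80)
        h = select_n_lv(X, y, max_lv=10, seed=0)
        assert h <= 3

    def test_stable_across_cv_seeds(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(60, 3))
        X = scores @ rng.normal(size=(3, 15)) + rng.normal(0, 0.05, (60, 15))
        y = scores @ np.array([2.0, 1.0, -1.0]) + rng.normal(0, 0.05, 60)
        picks = {select_n_lv(X, y, max_lv=8, seed=s) for s in range(5)}
        assert max(picks) - min(picks) <= 1


class TestGridSearch:
    def test_known_convex_objective(self):
        res = grid_search_lssvm(None, None, objective=lambda g, s: (g - 2) ** 2 + (s + 3) ** 2)
        assert res.log2_gamma == pytest.approx(2.0, abs=0.1)
        assert res.log2_inv_sigma2 == pytest.approx(-3.0, abs=0.1)

    def test_coarse_grid_has_289_points(self):
        calls = []

        def objective(g, s):
            calls.append((g, s))
            return g**2 + s**2

        res = grid_search_lssvm(None, None, objective=objective)
        assert res.n_coarse_evals == 289  # 17 x 17 unit grid on [-8, 8]^2
        assert len(calls) == res.n_coarse_evals + res.n_fine_evals

    def test_fine_stage_never_worse(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 6))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.05, 25)
        res = grid_search_lssvm(X, y, k=5, seed=0)
        assert res.rmsecv <= res.coarse_rmsecv

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            grid_search_lssvm(None, None, log2_range=(3, 3), objective=lambda g, s: 0.0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == 1.0 and m.rmse == 0.0

    def test_null_model_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        m = compute_metrics([0.0, 10.0], [1.0, 9.0])
        assert m.rmse == pytest.approx(1.0)
        assert m.r2 == pytest.approx(0.96)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([2.0, 2.0], [1.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0, 2.0])


class TestSerialization:
    def test_plsr_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        X, y = _random_problem(rng)
        model = fit_plsr(X, y, n_lv=4)
        save_model(model, tmp_path / "m.h5", preprocessing={"snv": True, "crop_nm": 435.0})
        back, prep = load_model(tmp_path / "m.h5")
        assert prep == {"snv": True, "crop_nm": 435.0}
        assert np.allclose(back.predict(X), model.predict(X))

    def test_lssvm_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        X, y = _random_problem(rng, n=20, p=3)
        model = fit_lssvm(X, y, gamma=5.0, sigma=1.5)
        save_model(model, tmp_path / "m.h5")
        back, _ = load_model(tmp_path / "m.h5")
        assert np.allclose(back.predict(X), model.predict(X))
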