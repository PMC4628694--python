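import numpy as np
import pytest
from scipy.optimize import minimize

from icushock.model import (
    auc_score,
    compute_vifs,
    cross_validate,
    default_lambda_grid,
    finalize_model,
    fit_elastic_net_path,
    lambda_max,
    stratified_folds,
    vif_prune,
)


def orthonormal_standardized_design(n, p, seed=0):
    """Columns with mean 0, population sd 1, and X^T X / n = I."""
    rng = np.random.default_rng(seed)
    A = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    Q, _ = np.linalg.qr(A)
    X = Q[:, 1:] * np.sqrt(n)  # mean-0 (orthogonal to 1), pop sd 1
    assert np.allclose(X.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(X.T @ X / n, np.eye(p), atol=1e-10)
    return X


def lbfgs_elastic_net(X, y, lam, alpha_mix):
    """Independent oracle: smooth bound-constrained reformulation
    (beta = b+ - b-) solved with L-BFGS-B."""
    n, p = X.shape
    yc = y - y.mean()

    def objective(z):
        beta = z[:p] - z[p:]
        r = yc - X @ beta
        return (0.5 / n * r @ r
                + lam * alpha_mix * z.sum()
                + lam * (1 - alpha_mix) / 2 * beta @ beta)

    def grad(z):
        beta = z[:p] - z[p:]
        g_beta = -X.T @ (yc - X @ beta) / n + lam * (1 - alpha_mix) * beta
        g = np.concatenate([g_beta, -g_beta]) + lam * alpha_mix
        return g

    res = minimize(objective, np.zeros(2 * p), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * p,
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x[:p] - res.x[p:]


class TestElasticNetPath:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 12))
        y = rng.normal(size=50)
        lams = default_lambda_grid(X, y, 0.5)
        path = fit_elastic_net_path((X, y), 0.5, lams)
        assert np.all(path.coefficients[0] == 0.0)
        assert lams[0] == pytest.approx(lambda_max(X, y, 0.5))

    def test_lasso_closed_form_on_orthonormal_design(self):
        n, p = 60, 6
        X = orthonormal_standardized_design(n, p)
        rng = np.random.default_rng(2)
        beta_true = np.array([2.0, -1.5, 1.0, 0.0, 0.4, 0.0])
        y = X @ beta_true + 0.1 * rng.normal(size=n)
        beta_ols = X.T @ (y - y.mean()) / n
        for lam in (0.05, 0.3, 0.8):
            path = fit_elastic_net_path((X, y), 1.0,
                                        np.array([lam]), tol=1e-12)
            expected = np.sign(beta_ols) * np.maximum(
                np.abs(beta_ols) - lam, 0.0)
            assert np.allclose(path.coefficients[0], expected, atol=1e-9)

    def test_ridge_limit_on_orthonormal_design(self):
        n, p = 60, 6
        X = orthonormal_standardized_design(n, p)
        rng = np.random.default_rng(3)
        y = X @ np.array([2.0, -1.5, 1.0, 0.0, 0.4, 0.0]) \
            + 0.1 * rng.normal(size=n)
        beta_ols = X.T @ (y - y.mean()) / n
        lam = 0.7
        alpha = 1e-8  # alpha_mix -> 0 limit
        path = fit_elastic_net_path((X, y), alpha, np.array([lam]),
                                    tol=1e-12)
        assert np.allclose(path.coefficients[0], beta_ols / (1 + lam),
                           atol=1e-6)

    @pytest.mark.parametrize("alpha_mix", [0.2, 0.5, 1.0])
    def test_matches_generic_convex_optimizer(self, alpha_mix):
        rng = np.random.default_rng(4)
        n, p = 40, 10
        X = rng.normal(size=(n, p))
        beta_true = np.zeros(p)
        beta_true[:3] = [1.5, -2.0, 1.0]
        y = X @ beta_true + rng.normal(size=n)
        # solver standardizes internally; give the oracle the same design
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        lmax = lambda_max(X, y, alpha_mix)
        for lam in (0.5 * lmax, 0.1 * lmax, 0.01 * lmax):
            path = fit_elastic_net_path((X, y), alpha_mix,
                                        np.array([lam]), tol=1e-12)
            oracle = lbfgs_elastic_net(Xs, y, lam, alpha_mix)
            assert np.allclose(path.coefficients[0], oracle, atol=1e-5)

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        X[:, 2] = 7.0
        y = rng.normal(size=40)
        path = fit_elastic_net_path((X, y), 0.5)
        assert np.all(path.coefficients[:, 2] == 0.0)

    def test_nonfinite_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_elastic_net_path((X, np.ones(10)), 0.5)

    def test_bad_alpha_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="alpha_mix"):
            fit_elastic_net_path((X, np.ones(10)), 0.0)


class TestCrossValidate:
    def _separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.5).astype(float)
        X = rng.normal(size=(n, 5))
        X[:, 0] = 2.0 * y - 1.0  # feature equals the label (scaled)
        return X, y

    def test_separable_reaches_zero_error(self):
        X, y = self._separable()
        curve = cross_validate((X, y), 0.5, 5, seed=0)
        assert curve.cv_error.min() == 0.0

    def test_one_se_rule_invariants(self):
        X, y = self._separable(seed=3)
        curve = cross_validate((X, y), 0.5, 4, seed=1)
        assert curve.lambda_1se >= curve.lambda_min
        i_min = int(np.argmin(np.abs(curve.lambdas - curve.lambda_min)))
        i_1se = int(np.argmin(np.abs(curve.lambdas - curve.lambda_1se)))
        assert curve.cv_error[i_1se] <= (curve.cv_error[i_min]
                                         + curve.cv_se[i_min] + 1e-12)

    def test_null_error_matches_prevalence(self):
        rng = np.random.default_rng(0)
        errors = []
        for seed in range(20):
            n = 100
            y = np.zeros(n)
            y[:27] = 1.0
            rng.shuffle(y)
            X = rng.normal(size=(n, 10))
            curve = cross_validate((X, y), 0.5, 5, seed=seed)
            errors.append(curve.cv_error[0])  # largest lambda: null model
        assert np.mean(errors) == pytest.approx(0.27, abs=0.03)

    def test_same_seed_same_curve(self):
        X, y = self._separable(seed=5)
        c1 = cross_validate((X, y), 0.5, 3, seed=9)
        c2 = cross_validate((X, y), 0.5, 3, seed=9)
        assert np.array_equal(c1.cv_error, c2.cv_error)
        assert c1.lambda_1se == c2.lambda_1se

    def test_stratification_keeps_both_classes(self):
        y = np.array([1.0] * 5 + [0.0] * 45)
        for fold in stratified_folds(y, 5, seed=0):
            assert y[fold].sum() == 1.0

    def test_too_few_class_members_errors(self):
        y = np.array([1.0, 1.0] + [0.0] * 20)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_folds(y, 3, seed=0)


class TestVif:
    def test_duplicated_column_removed_with_inf_vif(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        X[:, 2] = X[:, 0]
        kept, removed, vifs = vif_prune(X, ["a", "b", "c"])
        assert removed == ["c"]  # later feature on ties
        assert kept == ["a", "b"]
        assert max(vifs.values()) <= 5.0

    def test_orthogonal_columns_all_kept(self):
        n = 64
        X = orthonormal_standardized_design(n, 4)
        kept, removed, vifs = vif_prune(X, list("abcd"))
        assert removed == []
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in vifs.values())

    def test_correlated_triple_terminates_under_threshold(self):
        rng = np.random.default_rng(1)
        n = 200
        z = rng.normal(size=n)
        X = np.column_stack([z + 0.18 * rng.normal(size=n) for _ in range(3)])
        # confirm the construction is strongly collinear
        assert np.corrcoef(X.T).min() > 0.9
        kept, removed, vifs = vif_prune(X, ["a", "b", "c"])
        assert len(removed) >= 1
        assert max(vifs.values()) <= 5.0
        # independent check: recompute VIFs of the kept block directly
        cols = [i for i, f in enumerate(["a", "b", "c"]) if f in kept]
        assert np.max(compute_vifs(X[:, cols])) <= 5.0

    def test_terminates_on_random_designs(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 80, 12
            base = rng.normal(size=(n, 4))
            mix = rng.normal(size=(4, p))
            X = base @ mix + 0.3 * rng.normal(size=(n, p))
            kept, removed, vifs = vif_prune(X, [f"f{i}" for i in range(p)])
            assert len(removed) <= p
            assert max(vifs.values()) <= 5.0

    def test_n_le_p_prunes_from_tail(self):
        # with n <= p everything is exactly collinear: all VIFs infinite,
        # the tie-break removes later features until VIF is defined
        X = np.random.default_rng(0).normal(size=(5, 6))
        kept, removed, vifs = vif_prune(X, [f"f{i}" for i in range(6)])
        assert removed[:2] == ["f5", "f4"]
        assert len(kept) < 5
        assert max(vifs.values()) <= 5.0


class TestAucAndFinalize:
    def test_rank_perfect_ordering(self):
        assert auc_score(np.array([1, 1, 0, 0]),
                         np.array([0.9, 0.8, 0.3, 0.2])) == 1.0

    def test_reversed_ordering(self):
        assert auc_score(np.array([0, 0, 1, 1]),
                         np.array([0.9, 0.8, 0.3, 0.2])) == 0.0

    def test_ties_give_half(self):
        assert auc_score(np.array([1, 0]), np.array([0.5, 0.5])) == 0.5

    def test_perfect_separation_auc_one(self):
        rng = np.random.default_rng(0)
        n = 40
        y = (rng.random(n) < 0.4).astype(float)
        X = (2 * y - 1).reshape(-1, 1) + 0.01 * rng.normal(size=(n, 1))
        coef, mse, auc_mean, auc_sd = finalize_model((X, y), ["f"], seed=0)
        assert auc_mean == 1.0
        assert auc_sd == 0.0
        assert mse < 0.01

    def test_null_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            y = (rng.random(n) < 0.3).astype(float)
            X = rng.normal(size=(n, 3))  # independent of y
            _, _, auc_mean, _ = finalize_model((X, y), list("abc"),
                                               seed=seed)
            aucs.append(auc_mean)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            finalize_model((np.ones((10, 1)), np.ones(10)), [], seed=0)

    def test_refit_needs_more_rows_than_features(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 5))
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="cannot refit"):
            finalize_model((X, y), list("abcde"), seed=0)
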