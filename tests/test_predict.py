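"""Ridge prediction: closed form, penalty selection, evaluation protocols."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hare import (
    InputError,
    accuracy,
    default_lambda_grid,
    evaluate_cross_panel,
    evaluate_within_panel,
    fit_ridge,
    select_lambda_cv,
)


def ridge_objective_oracle(X, y, lam):
    """Iterative-optimizer solution of the ridge objective on the
    standardised scale (independent of the closed form)."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    yc = y - y.mean()

    def obj(b):
        r = yc - Xs @ b
        return float(r @ r + lam * b @ b)

    def grad(b):
        return -2 * Xs.T @ (yc - Xs @ b) + 2 * lam * b

    res = minimize(obj, np.zeros(X.shape[1]), jac=grad, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x


class TestFitRidge:
    def test_lambda_zero_matches_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = fit_ridge(X, y, 0.0)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        beta, *_ = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)
        np.testing.assert_allclose(model.beta, beta, atol=1e-8)

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        lam = 1e8 * np.linalg.norm(X.T @ X)
        model = fit_ridge(X, y, lam)
        assert np.linalg.norm(model.beta) <= 1e-6
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-5)

    def test_matches_iterative_oracle_wide_matrix(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        lam = 3.7
        model = fit_ridge(X, y, lam)
        np.testing.assert_allclose(
            model.beta, ridge_objective_oracle(X, y, lam), atol=1e-6
        )

    def test_primal_and_dual_agree(self):
        rng = np.random.default_rng(3)
        lam = 2.5
        X = rng.normal(size=(40, 15))
        y = rng.normal(size=40)
        primal = fit_ridge(X, y, lam).beta  # p < n path
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        yc = y - y.mean()
        dual = Xs.T @ np.linalg.solve(Xs @ Xs.T + lam * np.eye(40), yc)
        np.testing.assert_allclose(primal, dual, atol=1e-8)

    def test_matches_sklearn_reference(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        lam = 1.3
        model = fit_ridge(X, y, lam)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        ref = Ridge(alpha=lam, fit_intercept=True).fit(Xs, y)
        np.testing.assert_allclose(model.beta, ref.coef_, atol=1e-8)

    def test_predictions_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        X2 = X.copy()
        X2[:, 0] = 100.0 * X2[:, 0] - 7.0
        p1 = fit_ridge(X, y, 1.0).predict(X)
        p2 = fit_ridge(X2, y, 1.0).predict(X2)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_ridge(X, rng.normal(size=20), 1.0)
        assert len(model.beta) == 2

    def test_negative_lambda_errors(self):
        with pytest.raises(InputError):
            fit_ridge(np.ones((5, 2)), np.ones(5), -1.0)


class TestSelectLambda:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        assert select_lambda_cv(X, y, grid=[2.5], k_folds=5) == 2.5

    def test_pure_noise_prefers_heavy_shrinkage(self):
        # transcriptome-like regime (features >> lines): with nothing to fit,
        # the CV curve decreases toward the null model through the whole grid
        grid = np.geomspace(1e-4, 1e4, 100)
        top = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 2000))
            y = rng.normal(size=200)
            lam = select_lambda_cv(X, y, grid=grid, k_folds=10, seed=seed)
            if lam >= grid[int(0.9 * len(grid))]:
                top += 1
        assert top >= 4

    def test_noise_free_linear_prefers_light_shrinkage(self):
        grid = np.geomspace(1e-4, 1e4, 50)
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(120, 10))
            y = X @ rng.normal(size=10)
            lam = select_lambda_cv(X, y, grid=grid, k_folds=10, seed=seed)
            if lam <= grid[int(0.1 * len(grid))]:
                low += 1
        assert low >= 16

    def test_too_few_lines_errors(self):
        with pytest.raises(InputError):
            select_lambda_cv(np.ones((5, 2)), np.ones(5), grid=[1.0], k_folds=10)


class TestAccuracy:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -y) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert accuracy([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_invariant_to_monotone_linear_transform(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=20)
        pred = obs + rng.normal(size=20)
        assert accuracy(obs, 3.0 * pred + 7.0) == pytest.approx(accuracy(obs, pred))

    def test_constant_vector_errors(self):
        with pytest.raises(InputError):
            accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWithinPanel:
    def test_noise_free_linear_trait_predicted(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 8))
        y = X @ rng.normal(size=8)
        res = evaluate_within_panel(X, y, n_repeats=5, seed=1)
        assert res.mean_accuracy >= 0.99

    def test_default_repeat_count_is_20(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=60)
        res = evaluate_within_panel(X, y, seed=2)
        assert len(res.accuracies) == 20

    def test_null_trait_accuracy_centered_on_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(250, 20))
        y = rng.normal(size=250)
        res = evaluate_within_panel(X, y, n_repeats=20, seed=4)
        assert abs(res.mean_accuracy) <= 0.1

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=50)
        a = evaluate_within_panel(X, y, n_repeats=4, seed=9)
        b = evaluate_within_panel(X, y, n_repeats=4, seed=9)
        assert a.accuracies == b.accuracies
        assert a.manifest["split_hash"] == b.manifest["split_hash"]


class TestCrossPanel:
    def test_family_stratified_subset_size(self):
        rng = np.random.default_rng(0)
        lines = [f"F{f:02d}_R{r:02d}" for f in range(25) for r in range(20)]
        X = pd.DataFrame(rng.normal(size=(500, 6)), index=lines)
        beta = rng.normal(size=6)
        y = pd.Series(X.to_numpy() @ beta, index=lines)
        Xte = pd.DataFrame(rng.normal(size=(40, 6)), index=[f"T{i}" for i in range(40)])
        yte = pd.Series(Xte.to_numpy() @ beta, index=Xte.index)
        fam = pd.Series({l: l.split("_")[0] for l in lines})
        res = evaluate_cross_panel(
            X, y, Xte, yte, family_map=fam, per_family=10, n_subsets=3, seed=1
        )
        assert len(res.accuracies) == 3
        assert res.manifest["per_family"] == 10
        # 25 families x 10 lines = 250-line training subsets
        assert res.mean_accuracy > 0.95

    def test_identical_features_noise_free_accuracy_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5)
        res = evaluate_cross_panel(X, y, X.copy(), y.copy(), seed=2)
        assert res.mean_accuracy >= 0.999

    def test_overlapping_lines_removed_from_test(self):
        rng = np.random.default_rng(2)
        idx = [f"l{i}" for i in range(50)]
        X = pd.DataFrame(rng.normal(size=(50, 4)), index=idx)
        y = pd.Series(X.to_numpy() @ rng.normal(size=4) + rng.normal(size=50), index=idx)
        Xte = pd.concat([X.iloc[:10], pd.DataFrame(
            rng.normal(size=(30, 4)), index=[f"t{i}" for i in range(30)],
            columns=X.columns)])
        yte = pd.Series(rng.normal(size=40), index=Xte.index)
        res = evaluate_cross_panel(X, y, Xte, yte, seed=3)
        assert res.manifest["overlapping_lines_removed"] == 10

    def test_short_family_sampled_at_size_with_warning(self):
        rng = np.random.default_rng(4)
        lines = [f"F00_R{r}" for r in range(4)] + [f"F01_R{r}" for r in range(12)]
        X = pd.DataFrame(rng.normal(size=(16, 3)), index=lines)
        y = pd.Series(X.to_numpy() @ rng.normal(size=3) + 0.1 * rng.normal(size=16),
                      index=lines)
        Xte = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"t{i}" for i in range(20)],
                           columns=X.columns)
        yte = pd.Series(rng.normal(size=20), index=Xte.index)
        fam = pd.Series({l: l.split("_")[0] for l in lines})
        with pytest.warns(UserWarning, match="smaller than per_family"):
            res = evaluate_cross_panel(
                X, y, Xte, yte, family_map=fam, per_family=10, n_subsets=2,
                seed=5, k_folds=3,
            )
        assert len(res.accuracies) == 2

    def test_feature_mismatch_errors(self):
        X = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        Xte = pd.DataFrame(np.ones((10, 2)), columns=["a", "c"])
        with pytest.raises(InputError):
            evaluate_cross_panel(X, np.ones(10), Xte, np.ones(10))


def test_default_grid_spans_heuristic_scale():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 10))
    grid = default_lambda_grid(X, num=100)
    assert len(grid) == 100
    assert grid[0] < 1e-2 < 1e2 < grid[-1]
    assert np.all(np.diff(grid) > 0)
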