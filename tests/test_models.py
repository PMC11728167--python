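"""ML layer: kernel formulas, stepwise regression, grid search, importance."""

import numpy as np
import pandas as pd
import pytest

from kernelbreak.features import FEATURE_NAMES
from kernelbreak.metrics import regression_report
from kernelbreak.models import (
    KNNParams,
    ModelError,
    SVMParams,
    feature_importance,
    fit_default,
    fit_stepwise_poly,
    grid_search_fit,
    knn_regress,
    make_estimator,
    svm_kernel_eval,
)


class TestKernelFormulas:
    def test_rbf_at_identical_points_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert svm_kernel_eval("rbf", x, x) == pytest.approx(1.0)

    def test_rbf_matches_gaussian_form(self):
        p = SVMParams(gamma=0.5)  # sigma = 1
        x, y = np.array([0.0, 0.0]), np.array([1.0, 1.0])
        assert svm_kernel_eval("rbf", x, y, p) == pytest.approx(np.exp(-1.0))

    def test_poly_degree_one_is_dot_product(self):
        p = SVMParams(degree=1)
        x, y = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert svm_kernel_eval("poly", x, y, p) == pytest.approx(11.0)

    def test_sigmoid_zero_argument(self):
        p = SVMParams(lam=1.0, xi=-11.0)
        x, y = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert svm_kernel_eval("sigmoid", x, y, p) == pytest.approx(0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ModelError):
            svm_kernel_eval("rbf", np.zeros(2), np.zeros(3))

    def test_invalid_params_rejected(self):
        with pytest.raises(ModelError):
            SVMParams(C=-1.0)
        with pytest.raises(ModelError):
            SVMParams(gamma=0.0)


class TestKnnRegress:
    def test_uniform_mean(self):
        assert knn_regress([2, 4, 6], KNNParams(K=3)) == pytest.approx(4.0)

    def test_equal_targets_any_weighting(self):
        assert knn_regress([5, 5, 5], KNNParams(K=3)) == 5.0
        assert knn_regress(
            [5, 5, 5], KNNParams(K=3, weighting="distance"), distances=[1, 2, 3]
        ) == 5.0

    def test_zero_distance_neighbor_dominates(self):
        out = knn_regress(
            [10.0, 99.0], KNNParams(K=2, weighting="distance"), distances=[0.0, 1.0]
        )
        assert out == 10.0

    def test_empty_targets_rejected(self):
        with pytest.raises(ModelError):
            knn_regress([], KNNParams(K=1))


def _poly_frame(n, rng, noise=0.0):
    X = pd.DataFrame(rng.uniform(1, 10, (n, 7)), columns=list(FEATURE_NAMES))
    y = 2.0 * X["S"].to_numpy() + noise * rng.normal(size=n)
    return X, y


class TestStepwisePoly:
    def test_recovers_linear_area_signal(self, rng):
        X, y = _poly_frame(60, rng)
        model = fit_stepwise_poly(X, y)
        assert any("S" in term for term in model.chosen_params["selected_terms"])
        rep = regression_report(y, model.predict(X))
        assert rep.r >= 0.999

    def test_pure_noise_target_stays_parsimonious(self):
        # AIC should not admit more than a couple of spurious quadratic terms
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.uniform(0, 1, (40, 7)), columns=list(FEATURE_NAMES))
            y = rng.normal(size=40)
            model = fit_stepwise_poly(X, y)
            sizes.append(len(model.chosen_params["selected_terms"]))
        assert np.median(sizes) <= 2

    def test_refit_is_deterministic(self, rng):
        X, y = _poly_frame(50, rng, noise=0.5)
        m1 = fit_stepwise_poly(X, y)
        m2 = fit_stepwise_poly(X, y)
        assert m1.chosen_params["selected_terms"] == m2.chosen_params["selected_terms"]
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_too_few_rows_rejected(self, rng):
        X, y = _poly_frame(8, rng)
        with pytest.raises(ModelError):
            fit_stepwise_poly(X, y)


class TestGridSearch:
    def test_single_point_grid_equals_direct_fit(self, rng):
        X, y = _poly_frame(50, rng, noise=0.1)
        grid = {"n_neighbors": [3], "weights": ["uniform"], "p": [2]}
        model = grid_search_fit(X, y, "regression", "KNN", grid=grid, seed=0)
        direct = make_estimator("regression", "KNN", {"n_neighbors": 3, "weights": "uniform", "p": 2})
        direct.fit(X.to_numpy(), y)
        assert np.allclose(model.predict(X), direct.predict(X.to_numpy()))

    def test_chosen_params_member_of_grid_and_argmin(self, rng):
        X, y = _poly_frame(60, rng, noise=0.5)
        grid = {"n_neighbors": [1, 3, 5], "weights": ["uniform", "distance"], "p": [1, 2]}
        model = grid_search_fit(X, y, "regression", "KNN", grid=grid, seed=0)
        for key, value in model.chosen_params.items():
            assert value in grid[key]
        log = model.cv_results
        assert len(log) == 12
        assert model.cv_score == pytest.approx(log["cv_score"].min())

    def test_staged_rf_scores_match_direct_fits(self, rng):
        # the prefix-of-a-forest shortcut must equal direct fits with the
        # same seed at every n_estimators grid point
        X, y = _poly_frame(40, rng, noise=0.5)
        grid = {"n_estimators": [10, 25], "max_depth": [3]}
        staged = grid_search_fit(X, y, "regression", "RF", grid=grid, seed=5)
        for n_est in (10, 25):
            direct = grid_search_fit(
                X, y, "regression", "RF",
                grid={"n_estimators": [n_est], "max_depth": [3]}, seed=5,
            )
            row = staged.cv_results.loc[staged.cv_results["n_estimators"] == n_est]
            assert row["cv_score"].iloc[0] == pytest.approx(direct.cv_score, abs=1e-12)

    def test_staged_lgbm_scores_match_direct_fits(self, rng):
        X, y = _poly_frame(60, rng, noise=0.5)
        grid = {"n_estimators": [20, 50], "colsample_bytree": [0.5]}
        staged = grid_search_fit(X, y, "regression", "LGBM", grid=grid, seed=5)
        for n_est in (20, 50):
            direct = grid_search_fit(
                X, y, "regression", "LGBM",
                grid={"n_estimators": [n_est], "colsample_bytree": [0.5]}, seed=5,
            )
            row = staged.cv_results.loc[staged.cv_results["n_estimators"] == n_est]
            assert row["cv_score"].iloc[0] == pytest.approx(direct.cv_score, rel=1e-9)

    def test_same_seed_reproduces_choice_and_predictions(self, small_dataset):
        X, y = small_dataset.xy("calibration", "class")
        grid = {"kernel": ["rbf", "linear"], "C": [1, 10], "gamma": [0.1]}
        m1 = grid_search_fit(X, y, "classification", "SVM", grid=grid, seed=2018)
        m2 = grid_search_fit(X, y, "classification", "SVM", grid=grid, seed=2018)
        assert m1.chosen_params == m2.chosen_params
        Xp, _ = small_dataset.xy("prediction", "class")
        assert np.array_equal(m1.predict(Xp), m2.predict(Xp))

    def test_classification_fold_requires_both_classes(self):
        X = pd.DataFrame(np.random.default_rng(0).uniform(size=(12, 7)),
                         columns=list(FEATURE_NAMES))
        y = np.array(["broken"] * 10 + ["unbroken"] * 2)
        with pytest.raises(ModelError):
            grid_search_fit(X, y, "classification", "KNN",
                            grid={"n_neighbors": [1]}, folds=5, seed=0)

    def test_noise_free_monotone_recovery_all_algorithms(self):
        # with the weight noise off, mass is an exact monotone function of
        # projected area; every algorithm should track it nearly perfectly
        from kernelbreak.synth import WeightModel, generate_dataset

        ds = generate_dataset(
            n_broken=60, n_unbroken=60, seed=31, weight_model=WeightModel(sigma=0.0)
        )
        X, y = ds.xy("calibration", "weight")
        Xh, yh = ds.xy("prediction", "weight")
        small_grids = {
            "SPR": {},
            "RF": {"n_estimators": [200], "max_depth": [8]},
            "SVM": {"kernel": ["rbf"], "C": [10], "gamma": [0.01, 0.1]},
            "LGBM": {"n_estimators": [300], "colsample_bytree": [0.6]},
            "KNN": {"n_neighbors": [3], "weights": ["distance"], "p": [2]},
        }
        for algo, grid in small_grids.items():
            if algo == "SPR":
                model = fit_stepwise_poly(X, y)
            else:
                model = grid_search_fit(X, y, "regression", algo, grid=grid, seed=1)
            rep = regression_report(yh, model.predict(Xh))
            assert rep.r >= 0.95, f"{algo} failed noise-free recovery (r={rep.r:.3f})"


class TestPredictContract:
    def test_batch_equals_rowwise(self, small_dataset):
        X, y = small_dataset.xy("calibration", "weight", "broken")
        model = fit_default("regression", "LGBM", X, y)
        batch = model.predict(X)
        rows = np.concatenate([model.predict(X.iloc[[i]]) for i in range(len(X))])
        assert np.allclose(batch, rows)

    def test_column_permutation_irrelevant_for_named_input(self, small_dataset):
        X, y = small_dataset.xy("calibration", "weight", "broken")
        model = fit_default("regression", "RF", X, y)
        shuffled = X[list(reversed(X.columns))]
        assert np.allclose(model.predict(X), model.predict(shuffled))

    def test_missing_columns_reported(self, small_dataset):
        X, y = small_dataset.xy("calibration", "weight", "broken")
        model = fit_default("regression", "RF", X, y)
        with pytest.raises(ModelError, match="S"):
            model.predict(X.drop(columns=["S"]))

    def test_regression_output_clipped_at_zero(self, rng):
        X, y = _poly_frame(40, rng)
        y = y - y.mean()  # force negative targets
        model = fit_stepwise_poly(X, y)
        assert (model.predict(X) >= 0).all()


class TestFeatureImportance:
    def test_noise_feature_has_negligible_importance(self, small_dataset):
        X, y = small_dataset.xy("calibration", "class")
        model = grid_search_fit(
            X, y, "classification", "RF",
            grid={"n_estimators": [100], "max_depth": [5]}, seed=0,
        )
        Xp, yp = small_dataset.xy("prediction", "class")
        Xp = Xp.copy()
        rng = np.random.default_rng(1)
        Xp["S"] = rng.uniform(0, 1, len(Xp))  # decouple S from the labels
        table = feature_importance(model, Xp, yp, seed=0)
        row = table.set_index("feature").loc["S"]
        assert abs(row["importance"]) <= 2 * row["importance_sd"] + 1e-9

    def test_importances_sorted_and_bounded(self, small_dataset):
        X, y = small_dataset.xy("calibration", "class")
        model = grid_search_fit(
            X, y, "classification", "RF",
            grid={"n_estimators": [100], "max_depth": [5]}, seed=0,
        )
        Xp, yp = small_dataset.xy("prediction", "class")
        table = feature_importance(model, Xp, yp, seed=0)
        imp = table["importance"].to_numpy()
        assert (np.diff(imp) <= 1e-12).all()
        assert (imp >= -0.05).all()
        assert np.isfinite(imp.sum())

    def test_regression_model_rejected(self, small_dataset):
        X, y = small_dataset.xy("calibration", "weight", "broken")
        model = fit_default("regression", "RF", X, y)
        with pytest.raises(ModelError):
            feature_importance(model, X, y)
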