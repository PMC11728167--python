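"""Weight-regression and defect-classification models.

Five regression algorithms (stepwise polynomial regression SPR, random
forest RF, support-vector regression SVM, gradient boosting LGBM, K-nearest
neighbours KNN) and four classifiers (RF, SVM, LGBM, KNN) are trained with
exhaustive hyperparameter grids screened by five-fold cross-validation
(RMSE for regression, accuracy for classification), then refit on the full
calibration split.

Distance- and kernel-based algorithms (SVM, KNN) see z-scored features
(training-split statistics); tree models and SPR use raw features.  The SVR
target is also z-scored so the default epsilon tube is meaningful on the
gram scale.  Grids over ``n_estimators`` are evaluated by staged prediction:
one fit at the largest tree count per fold scores every prefix, which for
both random forests and gradient boosting is exactly the model a direct fit
with that many trees would give at the same seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .features import FEATURE_NAMES

DEFAULT_SEED = 2018

REGRESSION_ALGORITHMS = ("SPR", "RF", "SVM", "LGBM", "KNN")
CLASSIFICATION_ALGORITHMS = ("RF", "SVM", "LGBM", "KNN")


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# kernel / neighbour primitives


@dataclass(frozen=True)
class SVMParams:
    """Support-vector kernel parameters.

    ``gamma`` relates to the RBF width sigma by gamma = 1 / (2 sigma^2).
    """

    kernel_kind: str = "rbf"
    C: float = 1.0
    gamma: float = 0.1
    degree: int = 3
    lam: float = 1.0
    xi: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ModelError("C and gamma must be positive")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ModelError("degree must be a positive integer")

    @property
    def sigma(self) -> float:
        return float(1.0 / np.sqrt(2.0 * self.gamma))


def svm_kernel_eval(kind: str, x, x_prime, params: SVMParams | None = None) -> float:
    """Evaluate one SVM kernel function: Gaussian RBF
    exp(-||x-x'||^2 / (2 sigma^2)), polynomial (x.x')^d, or sigmoid
    tanh(lambda x.x' + xi)."""
    params = params or SVMParams()
    x = np.asarray(x, dtype=float)
    xp = np.asarray(x_prime, dtype=float)
    if x.shape != xp.shape:
        raise ModelError("points must share dimensionality")
    if kind == "rbf":
        sigma = params.sigma
        if sigma == 0:
            raise ModelError("sigma must be nonzero")
        return float(np.exp(-np.sum((x - xp) ** 2) / (2 * sigma**2)))
    if kind == "poly":
        return float(np.dot(x, xp) ** params.degree)
    if kind == "sigmoid":
        return float(np.tanh(params.lam * np.dot(x, xp) + params.xi))
    if kind == "linear":
        return float(np.dot(x, xp))
    raise ModelError(f"unknown kernel kind {kind!r}")


@dataclass(frozen=True)
class KNNParams:
    K: int = 5
    weighting: str = "uniform"
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ModelError("K must be >= 1")
        if self.p < 1:
            raise ModelError("p must be >= 1")
        if self.weighting not in ("uniform", "distance"):
            raise ModelError(f"unknown weighting {self.weighting!r}")


def knn_regress(neighbor_targets, params: KNNParams | None = None, distances=None) -> float:
    """Aggregate K neighbour targets: arithmetic mean (uniform) or
    inverse-distance weighted mean; a zero-distance neighbour dominates."""
    params = params or KNNParams(K=len(neighbor_targets) or 1)
    y = np.asarray(neighbor_targets, dtype=float)
    if y.size == 0:
        raise ModelError("neighbor target list is empty")
    if params.weighting == "uniform":
        if y.size != params.K:
            raise ModelError(f"expected K={params.K} targets, got {y.size}")
        return float(y.mean())
    if distances is None:
        raise ModelError("distance weighting requires distances")
    d = np.asarray(distances, dtype=float)
    if (d == 0).any():
        return float(y[d == 0].mean())
    w = 1.0 / d
    return float(np.sum(w * y) / np.sum(w))


# ---------------------------------------------------------------------------
# stepwise polynomial regression


def _poly_terms(n_features: int, names: list[str]):
    terms = [((i,), names[i]) for i in range(n_features)]
    terms += [((i, i), f"{names[i]}^2") for i in range(n_features)]
    terms += [
        ((i, j), f"{names[i]}*{names[j]}")
        for i in range(n_features)
        for j in range(i + 1, n_features)
    ]
    return terms


class StepwisePolyRegressor:
    """Degree-2 polynomial regression with forward-backward AIC term selection.

    The candidate pool is the 7 linear terms, 7 squares and 21 pairwise
    products; term columns are z-scored internally for conditioning.  The
    search is deterministic: candidates are scanned in a fixed order and a
    step is taken only on a strict AIC improvement.
    """

    def __init__(self, feature_names=None, max_steps: int = 200):
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.max_steps = max_steps

    def get_params(self, deep=True):
        return {"feature_names": self.feature_names, "max_steps": self.max_steps}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        cols = [X[:, list(idx)].prod(axis=1) for idx, _ in self.terms_]
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    @staticmethod
    def _aic(y, resid_ss, k):
        n = len(y)
        return n * np.log(max(resid_ss, 1e-300) / n) + 2 * k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < 10:
            raise ModelError("stepwise regression needs >= 10 training rows")
        names = self.feature_names or [f"x{i}" for i in range(X.shape[1])]
        self.terms_ = _poly_terms(X.shape[1], list(names))
        design = self._design(X)
        self.mu_ = design.mean(axis=0)
        sd = design.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Z = (design - self.mu_) / self.sd_

        n = len(y)
        selected: list[int] = []
        sse0 = float(((y - y.mean()) ** 2).sum())
        best_aic = self._aic(y, sse0, 1)

        def fit_subset(idx):
            A = np.column_stack([np.ones(n)] + [Z[:, i] for i in idx])
            coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            return float((resid**2).sum()), coef, rank

        for _ in range(self.max_steps):
            improved = False
            # forward
            best_add, best_add_aic = None, best_aic
            for cand in range(Z.shape[1]):
                if cand in selected:
                    continue
                sse, _, rank = fit_subset(selected + [cand])
                if rank < len(selected) + 2:
                    continue  # aliased term adds no information
                aic = self._aic(y, sse, len(selected) + 2)
                if aic < best_add_aic - 1e-10:
                    best_add, best_add_aic = cand, aic
            if best_add is not None:
                selected.append(best_add)
                best_aic = best_add_aic
                improved = True
            # backward
            best_drop, best_drop_aic = None, best_aic
            for cand in list(selected):
                rest = [i for i in selected if i != cand]
                sse, _, _ = fit_subset(rest)
                aic = self._aic(y, sse, len(rest) + 1)
                if aic < best_drop_aic - 1e-10:
                    best_drop, best_drop_aic = cand, aic
            if best_drop is not None:
                selected.remove(best_drop)
                best_aic = best_drop_aic
                improved = True
            if not improved:
                break

        self.selected_ = sorted(selected)
        _, coef, _ = fit_subset(self.selected_)
        self.intercept_ = float(coef[0])
        self.coef_ = np.asarray(coef[1:], dtype=float)
        self.selected_terms_ = [self.terms_[i][1] for i in self.selected_]
        self.aic_ = best_aic
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Z = (self._design(X) - self.mu_) / self.sd_
        if not self.selected_:
            return np.full(len(X), self.intercept_)
        return self.intercept_ + Z[:, self.selected_] @ self.coef_


# ---------------------------------------------------------------------------
# estimator factory and grids


def default_grids() -> dict[str, dict[str, dict[str, list]]]:
    """Shipped hyperparameter grids per task and algorithm.

    LGBM, SVM and KNN grids are the full screening grids; the RF max_depth
    axis is a coarse ladder over 1..91 covering the depth-saturation range
    (the full integer axis can be supplied via config).
    """
    rf = {
        "n_estimators": list(range(400, 501, 5)),
        "max_depth": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 40, 91],
        "max_features": [1, 2, 3, 4, 5, 6],
    }
    lgbm = {
        "colsample_bytree": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
        "n_estimators": list(range(400, 1001, 10)),
    }
    svm = {
        "kernel": ["linear", "poly", "rbf", "sigmoid"],
        "C": [0.1, 1, 10],
        "gamma": [0.01, 0.1, 1],
    }
    knn = {
        "n_neighbors": [1, 2, 3, 4, 5, 6],
        "weights": ["distance", "uniform"],
        "p": [1, 2, 3, 4, 5, 6],
    }
    return {
        "regression": {"SPR": {}, "RF": rf, "SVM": svm, "LGBM": lgbm, "KNN": knn},
        "classification": {"RF": rf, "SVM": svm, "LGBM": lgbm, "KNN": knn},
    }


#: reported optima of the reference screening, shipped as fast defaults
DEFAULT_PARAMS = {
    ("regression", "LGBM"): {"colsample_bytree": 0.1, "n_estimators": 410},
    ("regression", "RF"): {
        "n_estimators": 435, "max_features": 5, "max_depth": 6, "min_samples_split": 2,
    },
}


def make_estimator(task: str, algorithm: str, params: dict | None = None, seed: int = DEFAULT_SEED):
    """Build an unfitted estimator for (task, algorithm) with given params."""
    params = dict(params or {})
    if task not in ("regression", "classification"):
        raise ModelError(f"unknown task {task!r}")
    if algorithm == "SPR":
        if task != "regression":
            raise ModelError("SPR is regression-only")
        return StepwisePolyRegressor(feature_names=list(FEATURE_NAMES), **params)
    if algorithm == "RF":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(random_state=seed, n_jobs=1, **params)
    if algorithm == "LGBM":
        cls = LGBMRegressor if task == "regression" else LGBMClassifier
        return cls(random_state=seed, n_jobs=1, verbose=-1, **params)
    if algorithm == "SVM":
        est = SVR(**params) if task == "regression" else SVC(random_state=seed, **params)
        steps = [("scale", StandardScaler()), ("svm", est)]
        if task == "regression":
            from sklearn.compose import TransformedTargetRegressor

            return TransformedTargetRegressor(
                regressor=Pipeline(steps), transformer=StandardScaler()
            )
        return Pipeline(steps)
    if algorithm == "KNN":
        cls = KNeighborsRegressor if task == "regression" else KNeighborsClassifier
        return Pipeline([("scale", StandardScaler()), ("knn", cls(**params))])
    raise ModelError(f"unknown algorithm {algorithm!r}")


def _set_params(task, algorithm, estimator, params):
    """Route plain param names into the (possibly nested) estimator."""
    if algorithm == "SVM":
        prefix = "regressor__svm__" if task == "regression" else "svm__"
        estimator.set_params(**{prefix + k: v for k, v in params.items()})
    elif algorithm == "KNN":
        estimator.set_params(**{"knn__" + k: v for k, v in params.items()})
    else:
        estimator.set_params(**params)
    return estimator


# ---------------------------------------------------------------------------
# trained model container


@dataclass
class TrainedModel:
    """A fitted regressor or classifier with its screening provenance."""

    task: str
    algorithm: str
    estimator: object
    feature_names: list[str]
    chosen_params: dict
    cv_score: float | None = None
    cv_results: pd.DataFrame | None = None
    seed: int = DEFAULT_SEED

    def _matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise ModelError(f"feature table is missing columns: {missing}")
            return features.loc[:, self.feature_names].to_numpy(dtype=float)
        arr = np.atleast_2d(np.asarray(features, dtype=float))
        if arr.shape[1] != len(self.feature_names):
            raise ModelError(
                f"expected {len(self.feature_names)} features, got {arr.shape[1]}"
            )
        return arr

    def predict(self, features):
        """Predict weights (grams, clipped at 0) or class labels."""
        X = self._matrix(features)
        with warnings.catch_warnings():
            # lightgbm invents Column_i names even for arrays; harmless
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            out = self.estimator.predict(X)
        if self.task == "regression":
            out = np.clip(np.asarray(out, dtype=float), 0.0, None)
        return out


def predict(model: TrainedModel, features):
    return model.predict(features)


# ---------------------------------------------------------------------------
# grid search with five-fold CV


def _fold_rmse(y_true, y_pred) -> float:
    resid = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
    return float(np.sqrt((resid**2).sum() / max(len(resid) - 1, 1)))


def _cv_splits(task, X, y, folds, seed):
    if task == "classification":
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < folds:
            raise ModelError(
                "stratified folding impossible: a class has fewer members than folds"
            )
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(kf.split(X, y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(X))


def _staged_axis(algorithm, grid):
    """Return the n_estimators axis if stage-wise evaluation applies."""
    if algorithm in ("LGBM", "RF") and "n_estimators" in grid and len(grid["n_estimators"]) > 1:
        return sorted(int(v) for v in grid["n_estimators"])
    return None


def _rf_staged_predict(est, X, tree_counts, task):
    # the first k trees of a forest are identical to a k-tree forest at the
    # same seed, so prefix averages score the whole n_estimators axis from
    # one fit; the low-level tree_.predict skips per-call validation
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    if task == "regression":
        preds = np.array(
            [t.tree_.predict(X32).reshape(len(X32), -1)[:, 0] for t in est.estimators_]
        )
        csum = np.cumsum(preds, axis=0)
        return {k: csum[k - 1] / k for k in tree_counts}
    # class-mass leaves, normalized per tree as predict_proba does
    proba = np.array(
        [
            (lambda v: v / v.sum(axis=1, keepdims=True))(
                t.tree_.predict(X32).reshape(len(X32), -1)
            )
            for t in est.estimators_
        ]
    )
    csum = np.cumsum(proba, axis=0)
    return {k: est.classes_[np.argmax(csum[k - 1], axis=1)] for k in tree_counts}


def grid_search_fit(
    X,
    y,
    task: str,
    algorithm: str,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> TrainedModel:
    """Exhaustive grid search by k-fold CV, refit of the winner on all rows.

    Scores are RMSE (regression, minimized) or accuracy (classification,
    maximized), averaged over folds; ties are broken by grid order.  The
    full per-grid-point score table is kept on the returned model
    (``cv_results``) as the training log.
    """
    if folds < 2:
        raise ModelError("folds must be >= 2")
    if grid is None:
        grid = default_grids()[task][algorithm]
    feature_names = (
        list(X.columns) if isinstance(X, pd.DataFrame) else list(FEATURE_NAMES)[: np.shape(X)[1]]
    )
    Xm = X.loc[:, feature_names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y)

    keys = list(grid.keys())
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))] or [{}]

    staged = _staged_axis(algorithm, grid)
    splits = _cv_splits(task, Xm, y, folds, seed)
    minimize = task == "regression"
    score_fn = _fold_rmse if minimize else (lambda a, b: float(np.mean(np.asarray(a) == np.asarray(b))))

    scores: dict[tuple, list[float]] = {tuple(sorted(c.items())): [] for c in combos}

    if staged is not None:
        other_keys = [k for k in keys if k != "n_estimators"]
        outer = [dict(zip(other_keys, v)) for v in itertools.product(*(grid[k] for k in other_keys))] or [{}]
        n_max = staged[-1]
        for combo in outer:
            for tr, va in splits:
                est = make_estimator(task, algorithm, seed=seed)
                _set_params(task, algorithm, est, {**combo, "n_estimators": n_max})
                est.fit(Xm[tr], y[tr])
                if algorithm == "LGBM":
                    with warnings.catch_warnings():
                        warnings.filterwarnings(
                            "ignore", message="X does not have valid feature names"
                        )
                        preds = {k: est.predict(Xm[va], num_iteration=k) for k in staged}
                else:
                    preds = _rf_staged_predict(est, Xm[va], staged, task)
                for k in staged:
                    full = {**combo, "n_estimators": k}
                    scores[tuple(sorted(full.items()))].append(score_fn(y[va], preds[k]))
    else:
        for combo in combos:
            for tr, va in splits:
                est = make_estimator(task, algorithm, seed=seed)
                _set_params(task, algorithm, est, combo)
                est.fit(Xm[tr], y[tr])
                scores[tuple(sorted(combo.items()))].append(score_fn(y[va], est.predict(Xm[va])))

    rows = []
    best_combo, best_score = None, None
    for combo in combos:  # grid order; strict comparison -> first best wins ties
        s = float(np.mean(scores[tuple(sorted(combo.items()))]))
        rows.append({**combo, "cv_score": s})
        better = best_score is None or (s < best_score if minimize else s > best_score)
        if better:
            best_combo, best_score = combo, s

    final = make_estimator(task, algorithm, seed=seed)
    _set_params(task, algorithm, final, best_combo)
    final.fit(Xm, y)
    return TrainedModel(
        task=task,
        algorithm=algorithm,
        estimator=final,
        feature_names=feature_names,
        chosen_params=dict(best_combo),
        cv_score=best_score,
        cv_results=pd.DataFrame(rows),
        seed=seed,
    )


def fit_stepwise_poly(X, y, seed: int = DEFAULT_SEED) -> TrainedModel:
    """Fit the stepwise quadratic-polynomial weight model (no grid)."""
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else list(FEATURE_NAMES)
    Xm = X.loc[:, feature_names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    est = StepwisePolyRegressor(feature_names=feature_names)
    est.fit(Xm, np.asarray(y, dtype=float))
    return TrainedModel(
        task="regression",
        algorithm="SPR",
        estimator=est,
        feature_names=feature_names,
        chosen_params={"selected_terms": est.selected_terms_},
        cv_score=None,
        seed=seed,
    )


def fit_default(task: str, algorithm: str, X, y, seed: int = DEFAULT_SEED) -> TrainedModel:
    """Direct fit with the shipped default hyperparameters (no search)."""
    if algorithm == "SPR":
        return fit_stepwise_poly(X, y, seed=seed)
    params = DEFAULT_PARAMS.get((task, algorithm), {})
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else list(FEATURE_NAMES)
    Xm = X.loc[:, feature_names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    est = make_estimator(task, algorithm, seed=seed)
    _set_params(task, algorithm, est, params)
    est.fit(Xm, np.asarray(y))
    return TrainedModel(
        task=task, algorithm=algorithm, estimator=est,
        feature_names=feature_names, chosen_params=params, seed=seed,
    )


# ---------------------------------------------------------------------------
# importance


def feature_importance(
    model: TrainedModel, X, y, n_repeats: int = 20, seed: int = DEFAULT_SEED
) -> pd.DataFrame:
    """Permutation importance (mean accuracy drop over shuffles) on held-out
    data; descending, ties broken by feature name."""
    from sklearn.inspection import permutation_importance

    if model.task != "classification":
        raise ModelError("feature importance is defined for classification models")
    if not hasattr(model, "estimator") or model.estimator is None:
        raise ModelError("model is not fitted")
    Xm = model._matrix(X)
    result = permutation_importance(
        model.estimator, Xm, np.asarray(y), scoring="accuracy",
        n_repeats=n_repeats, random_state=seed,
    )
    out = pd.DataFrame(
        {
            "feature": model.feature_names,
            "importance": result.importances_mean,
            "importance_sd": result.importances_std,
        }
    ).sort_values(["importance", "feature"], ascending=[False, True])
    return out.reset_index(drop=True)
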