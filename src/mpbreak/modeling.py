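"""Regressor benchmarking, final-model optimization and prediction bundles.

Twelve regressor families sit behind a uniform fit/predict contract and are
benchmarked with 5-fold nested cross-validation: the outer split (fixed by
seed and shared by every regressor-descriptor pair) estimates generalization
while an inner split selects hyperparameters, so the outer test folds never
influence model selection.

The final tree ensemble gets a post-hoc affine bias correction: ordinary
least squares of the training targets on the ensemble's raw training
predictions, countering the regression-to-the-mean compression of extreme
values typical of bagged trees.  Adjusted predictions
``slope * raw + intercept`` are the primary output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import AdaBoostRegressor, GradientBoostingRegressor, RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression, Ridge, SGDRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, ParameterSampler
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR, LinearSVR
from sklearn.tree import DecisionTreeRegressor

from .applicability import confidence_score, similarity_profile
from .descriptors import FingerprintMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressorSpec:
    name: str
    factory: Callable[[int], object]  # seed -> unfitted estimator
    grid: dict


def default_registry() -> dict[str, RegressorSpec]:
    """The twelve benchmark regressor families with small inner-CV grids."""
    specs = [
        RegressorSpec("MLR", lambda s: LinearRegression(), {}),
        RegressorSpec("Ridge", lambda s: Ridge(), {"alpha": [0.1, 1.0, 10.0]}),
        RegressorSpec("KR", lambda s: KernelRidge(kernel="rbf"),
                      {"alpha": [0.1, 1.0], "gamma": [0.01, 0.1]}),
        RegressorSpec("SGD", lambda s: SGDRegressor(random_state=s, max_iter=2000),
                      {"alpha": [1e-4, 1e-3]}),
        RegressorSpec("LSVR", lambda s: LinearSVR(random_state=s, max_iter=5000, dual="auto"),
                      {"C": [0.1, 1.0]}),
        RegressorSpec("RF", lambda s: RandomForestRegressor(random_state=s, n_jobs=1),
                      {"n_estimators": [100], "max_depth": [None, 10]}),
        RegressorSpec("GBR", lambda s: GradientBoostingRegressor(random_state=s),
                      {"n_estimators": [100], "max_depth": [2, 3]}),
        RegressorSpec("AB", lambda s: AdaBoostRegressor(random_state=s),
                      {"n_estimators": [50, 100]}),
        RegressorSpec("DT", lambda s: DecisionTreeRegressor(random_state=s),
                      {"max_depth": [None, 5, 10]}),
        RegressorSpec("MLP", lambda s: MLPRegressor(random_state=s, max_iter=700),
                      {"hidden_layer_sizes": [(64,)], "alpha": [1e-3]}),
        RegressorSpec("SVR", lambda s: SVR(kernel="rbf"), {"C": [1.0, 10.0]}),
        RegressorSpec("KNN", lambda s: KNeighborsRegressor(), {"n_neighbors": [3, 5, 10]}),
    ]
    return {s.name: s for s in specs}


def r2(y_true, y_pred) -> float:
    """Coefficient of determination with a fixed zero-variance convention.

    A fold whose true targets are constant has no variance to explain; its
    R² is defined as 0.0 (never 1.0, even for an exact constant match).
    """
    y_true = np.asarray(y_true, dtype=float)
    if np.ptp(y_true) == 0:
        return 0.0
    return float(r2_score(y_true, y_pred))


@dataclass
class BenchmarkResult:
    regressor_name: str
    descriptor_kind: str
    fold_r2: list[float]
    fold_rmse: list[float]
    fold_params: list[dict]
    seed: int
    n_outer: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def median_r2(self) -> float:
        return float(np.median(self.fold_r2))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.fold_rmse))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FingerprintMatrix):
        return X.to_frame()
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("X must be a FingerprintMatrix or a substance-indexed DataFrame")


def _descriptor_kind(X) -> str:
    return X.kind.value if isinstance(X, FingerprintMatrix) else "TABLE"


def _check_targets(y: pd.Series) -> None:
    bad = y.index[~np.isfinite(y.to_numpy(dtype=float))].tolist()
    if bad:
        raise ValueError(f"non-finite target values for substances: {bad[:10]}")


def outer_fold_assignments(ids: list[str], seed: int, n_outer: int = 5) -> dict[str, int]:
    """Deterministic outer-fold assignment, identical for every regressor."""
    kf = KFold(n_splits=n_outer, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(kf.split(ids)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return assignment


def nested_cv_benchmark(
    X,
    y: pd.Series,
    registry: dict[str, RegressorSpec] | None = None,
    seed: int = 0,
    regressors: list[str] | None = None,
    n_outer: int = 5,
    n_inner: int = 3,
    return_models: bool = False,
) -> list[BenchmarkResult] | tuple[list[BenchmarkResult], dict]:
    """Benchmark regressors with nested CV on a shared outer split.

    ``X`` rows and ``y`` must be aligned on substance id.  Results are
    sorted by decreasing mean R².  With ``return_models=True`` the
    per-fold fitted best estimators are returned as well (used for
    cross-fold feature importance).
    """
    Xf = _as_frame(X)
    y = y.loc[Xf.index]
    _check_targets(y)
    registry = registry or default_registry()
    names = regressors or list(registry)

    ids = list(Xf.index)
    assignment = outer_fold_assignments(ids, seed, n_outer)
    fold_of = np.array([assignment[i] for i in ids])
    Xa, ya = Xf.to_numpy(dtype=float), y.to_numpy(dtype=float)

    results: list[BenchmarkResult] = []
    fitted: dict[str, list] = {}
    for name in names:
        spec = registry[name]
        fold_r2, fold_rmse, fold_params, fold_models = [], [], [], []
        for fold in range(n_outer):
            train_mask = fold_of != fold
            X_tr, y_tr = Xa[train_mask], ya[train_mask]
            X_te, y_te = Xa[~train_mask], ya[~train_mask]
            est = spec.factory(seed)
            if spec.grid:
                inner = KFold(n_splits=n_inner, shuffle=True, random_state=seed)
                search = GridSearchCV(est, spec.grid, cv=inner, scoring="r2", n_jobs=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    search.fit(X_tr, y_tr)
                best = search.best_estimator_
                params = search.best_params_
            else:
                best = clone(est)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    best.fit(X_tr, y_tr)
                params = {}
            pred = best.predict(X_te)
            fold_r2.append(r2(y_te, pred))
            fold_rmse.append(float(np.sqrt(mean_squared_error(y_te, pred))))
            fold_params.append(params)
            fold_models.append(best)
        results.append(
            BenchmarkResult(name, _descriptor_kind(X), fold_r2, fold_rmse, fold_params,
                            seed, n_outer)
        )
        fitted[name] = fold_models
        logger.info("benchmark %s: mean R2=%.3f RMSE=%.3f", name,
                    results[-1].mean_r2, results[-1].mean_rmse)

    results.sort(key=lambda r: r.mean_r2, reverse=True)
    if return_models:
        return results, fitted
    return results


def y_scramble(
    X,
    y: pd.Series,
    n_repeats: int = 10,
    seed: int = 0,
    regressor: str = "RF",
    registry: dict[str, RegressorSpec] | None = None,
    n_outer: int = 5,
    n_inner: int = 3,
) -> dict:
    """Null distribution of nested-CV mean R² under permuted targets.

    Each repeat permutes the targets and reruns the *entire* nested-CV
    workflow (including hyperparameter selection).  Returns the null
    scores, the unscrambled score and its percentile within the null.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    Xf = _as_frame(X)
    y = y.loc[Xf.index]
    kwargs = dict(registry=registry, seed=seed, regressors=[regressor],
                  n_outer=n_outer, n_inner=n_inner)
    unscrambled = nested_cv_benchmark(X, y, **kwargs)[0].mean_r2
    rng = np.random.default_rng(seed)
    null_scores = []
    for _ in range(n_repeats):
        perm = rng.permutation(len(y))
        y_perm = pd.Series(y.to_numpy()[perm], index=y.index)
        null_scores.append(nested_cv_benchmark(X, y_perm, **kwargs)[0].mean_r2)
    null = np.array(null_scores)
    return {
        "null_scores": null,
        "unscrambled_score": unscrambled,
        "percentile": float(np.mean(null < unscrambled)),
    }


@dataclass(frozen=True)
class HyperSearchSpec:
    """Search space for the final forest; lists must be sorted ascending."""

    n_estimators: tuple[int, ...] = (50, 100, 200, 400)
    max_depth: tuple[int | None, ...] = (5, 10, 20, None)
    min_samples_split: tuple[int, ...] = (2, 5, 10)
    max_features: tuple[float | str, ...] = ("sqrt", 0.3, 1.0)
    n_random: int = 20

    def __post_init__(self):
        if not (self.n_estimators and self.max_depth and self.min_samples_split
                and self.max_features):
            raise ValueError("empty hyperparameter range")


def _simplicity_key(params: dict) -> tuple:
    depth = params.get("max_depth")
    return (
        params.get("n_estimators", 0),
        float("inf") if depth is None else depth,
        -params.get("min_samples_split", 2),
    )


def select_best(candidates: list[tuple[dict, float]], tie_tol: float = 1e-6) -> dict:
    """Pick the highest-scoring candidate, breaking ties toward simplicity.

    Within ``tie_tol`` of the best score, preference order is: fewer trees,
    then smaller depth, then *larger* min-samples-split.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    best_score = max(score for _, score in candidates)
    tied = [p for p, s in candidates if s >= best_score - tie_tol]
    return min(tied, key=_simplicity_key)


def optimize_final(
    X,
    y: pd.Series,
    spec: HyperSearchSpec | None = None,
    seed: int = 0,
    n_cv: int = 5,
    tie_tol: float = 1e-6,
) -> dict:
    """Two-stage forest hyperparameter search: random, then a local grid.

    Stage one samples ``spec.n_random`` combinations at random; stage two
    grids over the neighbors (one step in each range) of the stage-one
    winner.  Scores are ``n_cv``-fold CV mean R²; ties go to the simpler
    model.
    """
    spec = spec or HyperSearchSpec()
    Xf = _as_frame(X)
    y = y.loc[Xf.index]
    _check_targets(y)
    Xa, ya = Xf.to_numpy(dtype=float), y.to_numpy(dtype=float)
    cv = KFold(n_splits=n_cv, shuffle=True, random_state=seed)

    def score(params: dict) -> float:
        scores = []
        for train_idx, test_idx in cv.split(Xa):
            rf = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
            rf.fit(Xa[train_idx], ya[train_idx])
            scores.append(r2_score(ya[test_idx], rf.predict(Xa[test_idx])))
        return float(np.mean(scores))

    space = {
        "n_estimators": list(spec.n_estimators),
        "max_depth": list(spec.max_depth),
        "min_samples_split": list(spec.min_samples_split),
        "max_features": list(spec.max_features),
    }
    sampled = list(ParameterSampler(space, n_iter=spec.n_random, random_state=seed))
    stage1 = [(p, score(p)) for p in sampled]
    best1 = select_best(stage1, tie_tol)

    def neighbors(options: list, value) -> list:
        i = options.index(value)
        return sorted({options[j] for j in (i - 1, i, i + 1) if 0 <= j < len(options)},
                      key=options.index)

    local = []
    for ne in neighbors(space["n_estimators"], best1["n_estimators"]):
        for md in neighbors(space["max_depth"], best1["max_depth"]):
            for ms in neighbors(space["min_samples_split"], best1["min_samples_split"]):
                local.append({"n_estimators": ne, "max_depth": md,
                              "min_samples_split": ms,
                              "max_features": best1["max_features"]})
    seen = {tuple(sorted(p.items(), key=lambda kv: kv[0])) for p, _ in stage1}
    stage2 = list(stage1)
    for p in local:
        key = tuple(sorted(p.items(), key=lambda kv: kv[0]))
        if key not in seen:
            seen.add(key)
            stage2.append((p, score(p)))
    return select_best(stage2, tie_tol)


def fit_bias_correction(raw_train_predictions, y_train) -> tuple[float, float]:
    """OLS line mapping raw ensemble predictions to targets.

    Returns ``(slope, intercept)`` such that the adjusted prediction is
    ``slope * raw + intercept``.  Constant raw predictions degrade to an
    identity-slope mean shift with a warning.
    """
    raw = np.asarray(raw_train_predictions, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if raw.shape != y.shape or raw.ndim != 1:
        raise ValueError("raw predictions and targets must be equal-length 1-D vectors")
    if len(raw) < 3:
        raise ValueError("need at least 3 points to fit the bias correction")
    if not (np.isfinite(raw).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in bias-correction inputs")
    if np.ptp(raw) == 0:
        warnings.warn("constant raw predictions; using identity-slope correction")
        return 1.0, float(np.mean(y) - np.mean(raw))
    slope, intercept = np.polyfit(raw, y, 1)
    return float(slope), float(intercept)


@dataclass
class ModelBundle:
    """Everything needed to predict with confidence on new structures."""

    ensemble: RandomForestRegressor
    bias_slope: float
    bias_intercept: float
    feature_subset: list[str]
    training_fingerprints: FingerprintMatrix
    training_target_stats: dict
    training_tree_sd: np.ndarray
    metadata: dict = field(default_factory=dict)


def _per_tree_predictions(ensemble, Xa: np.ndarray) -> np.ndarray:
    return np.stack([tree.predict(Xa) for tree in ensemble.estimators_])


def train_bundle(
    X: FingerprintMatrix,
    y: pd.Series,
    params: dict | None = None,
    seed: int = 0,
    feature_subset: list[str] | None = None,
    metadata: dict | None = None,
) -> ModelBundle:
    """Train the final forest plus its bias-correction line on all of X, y.

    The bias line is fitted on the *training* fitted values only; the
    training fingerprints and tree-SD distribution are retained for the
    applicability-domain machinery.
    """
    Xf = X.to_frame()
    y = y.loc[Xf.index]
    _check_targets(y)
    if feature_subset is not None:
        missing = set(feature_subset) - set(Xf.columns)
        if missing:
            raise KeyError(f"feature subset not in matrix: {sorted(missing)[:5]}")
        Xf = Xf[list(feature_subset)]
    names = list(Xf.columns)
    Xa, ya = Xf.to_numpy(dtype=float), y.to_numpy(dtype=float)

    rf = RandomForestRegressor(random_state=seed, n_jobs=1, **(params or {}))
    rf.fit(Xa, ya)
    raw = rf.predict(Xa)
    slope, intercept = fit_bias_correction(raw, ya)
    tree_sd = _per_tree_predictions(rf, Xa).std(axis=0, ddof=0)

    train_fps = X.subset(list(Xf.index))
    return ModelBundle(
        ensemble=rf,
        bias_slope=slope,
        bias_intercept=intercept,
        feature_subset=names,
        training_fingerprints=train_fps,
        training_target_stats={"mean": float(np.mean(ya)), "sd": float(np.std(ya, ddof=1))},
        training_tree_sd=tree_sd,
        metadata={"seed": seed, "params": params or {},
                  "descriptor_kind": X.kind.value, **(metadata or {})},
    )


def predict_bundle(bundle: ModelBundle, X_new: FingerprintMatrix) -> pd.DataFrame:
    """Predict adjusted logB with confidence and similarity diagnostics.

    ``X_new`` must share the bundle's descriptor kind; full-width matrices
    are auto-sliced down to the bundle's feature subset by bit name.
    """
    if X_new.kind != bundle.training_fingerprints.kind:
        raise ValueError(
            f"descriptor kind mismatch: bundle {bundle.training_fingerprints.kind.value}, "
            f"input {X_new.kind.value}"
        )
    frame = X_new.to_frame()
    missing = set(bundle.feature_subset) - set(frame.columns)
    if missing:
        raise ValueError(f"input matrix lacks bundle features: {sorted(missing)[:5]}")
    Xa = frame[bundle.feature_subset].to_numpy(dtype=float)

    per_tree = _per_tree_predictions(bundle.ensemble, Xa)
    raw = per_tree.mean(axis=0)
    tree_sd = per_tree.std(axis=0, ddof=0)
    adjusted = bundle.bias_slope * raw + bundle.bias_intercept

    train_bits = bundle.training_fingerprints.bits
    nearest, nearest5 = [], []
    for row in X_new.bits:
        s1, s5 = similarity_profile(row, train_bits)
        nearest.append(s1)
        nearest5.append(s5)
    conf = [confidence_score(sd, bundle.training_tree_sd) for sd in tree_sd]

    return pd.DataFrame(
        {
            "substance_id": X_new.substance_ids,
            "raw_logB": raw,
            "adjusted_logB": adjusted,
            "B_pred": 10.0**adjusted,
            "tree_sd": tree_sd,
            "confidence": conf,
            "similarity_nearest": nearest,
            "similarity_nearest5": nearest5,
        }
    )


def compare_models(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Pairwise one-sided Wilcoxon signed-rank tests on per-fold R².

    Row (a, b) tests whether a's per-fold scores exceed b's; the reported
    ``median_diff`` is antisymmetric under swapping a and b.  No multiple-
    comparison correction is applied.
    """
    folds = {(r.seed, r.n_outer) for r in results}
    if len(folds) > 1:
        raise ValueError("benchmark results use different outer folds")
    rows = []
    for a in results:
        for b in results:
            diff = np.array(a.fold_r2) - np.array(b.fold_r2)
            if np.allclose(diff, 0):
                p = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = stats.wilcoxon(a.fold_r2, b.fold_r2, alternative="greater")
            rows.append(
                {
                    "regressor_a": a.regressor_name,
                    "regressor_b": b.regressor_name,
                    "median_diff": float(np.median(diff)),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def save_bundle(bundle: ModelBundle, path: str) -> None:
    """Serialize a bundle: joblib payload plus a human-readable JSON sidecar."""
    joblib.dump(bundle, path)
    meta = {
        "format_version": 1,
        "bias_slope": bundle.bias_slope,
        "bias_intercept": bundle.bias_intercept,
        "n_features": len(bundle.feature_subset),
        "n_training_substances": len(bundle.training_fingerprints.substance_ids),
        "training_target_stats": bundle.training_target_stats,
        "metadata": bundle.metadata,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_bundle(path: str) -> ModelBundle:
    bundle = joblib.load(path)
    if not isinstance(bundle, ModelBundle):
        raise TypeError(f"{path} does not contain a ModelBundle")
    return bundle
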