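"""Affinity regression models and uncertainty estimators.

The point predictor is a gradient-boosted tree ensemble (LightGBM) trained
with stratified 5-fold cross-validation on the binned training set; only
the fold model with the lowest validation RMSE is retained for prediction.
Hyperparameters come from a seeded TPE-style Bayesian search
(:func:`tune_hyperparameters`).

Prediction uncertainty comes from one of three estimators:

* ``forest_std`` — the standard deviation over the 200 per-tree predictions
  of a random-forest regressor fitted on the same data (the recommended
  method);
* ``ensemble_std`` — the standard deviation over the 5 cross-validation
  fold models' predictions;
* ``knn_dist`` — the mean feature-space distance (Manhattan or Euclidean)
  to the k in {1, 10} nearest training points.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import lightgbm as lgb
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import NearestNeighbors

from .dataset import SplitAssignment, binned_split, stratified_folds
from .descriptor import N_FEATURES

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SEARCH_SPACE",
    "DEFAULT_HYPERPARAMETERS",
    "AffinityRegressor",
    "ForestUncertainty",
    "EnsembleUncertainty",
    "KNNUncertainty",
    "tune_hyperparameters",
    "train_regressor",
    "train_uncertainty",
    "predict",
    "save_bundle",
    "load_bundle",
]

N_FOREST_TREES = 200

#: search space for the boosted-tree hyperparameters:
#: (low, high, log-scale?, integer?)
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float, bool, bool]] = {
    "learning_rate": (0.01, 0.3, True, False),
    "num_leaves": (8, 256, True, True),
    "max_depth": (3, 12, False, True),
    "min_child_samples": (5, 100, True, True),
    "subsample": (0.5, 1.0, False, False),
    "colsample_bytree": (0.5, 1.0, False, False),
    "reg_alpha": (1e-8, 10.0, True, False),
    "reg_lambda": (1e-8, 10.0, True, False),
}

DEFAULT_HYPERPARAMETERS: dict = {
    "learning_rate": 0.1,
    "num_leaves": 31,
    "max_depth": -1,
    "min_child_samples": 20,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "reg_alpha": 0.0,
    "reg_lambda": 0.0,
}


def _rmse(y_true, y_pred) -> float:
    err = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean(err**2)))


def _check_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(
            f"expected descriptors of width {N_FEATURES}, got shape {X.shape}"
        )
    return X


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _silent_predict(model, X: np.ndarray) -> np.ndarray:
    # the lightgbm sklearn wrapper records synthetic feature names even for
    # plain arrays and then warns on array input at predict time
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        return model.predict(X)


def _lgbm(params: dict, n_estimators: int, seed: int) -> lgb.LGBMRegressor:
    return lgb.LGBMRegressor(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
        subsample_freq=1,
        **params,
    )


class AffinityRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regressor for MCA/MAA values (kJ/mol).

    Fits one booster per cross-validation fold and predicts with the fold
    model that achieved the lowest validation RMSE.

    Parameters
    ----------
    property_tag : {"MCA", "MAA"}
        Which affinity the targets represent (metadata only).
    hyperparameters : dict or None
        LightGBM parameters; ``None`` uses :data:`DEFAULT_HYPERPARAMETERS`.
    n_estimators : int, default 300
        Boosting rounds per fold model.
    n_folds, n_bins : int
        Cross-validation folds and target bins used when ``fit`` has to
        derive folds itself.
    random_state : int
        Seeds fold assignment and the boosters.

    Attributes
    ----------
    models_ : list of fitted boosters, one per fold
    cv_rmse_ : list of per-fold validation RMSE (kJ/mol)
    best_fold_ : index of the retained model (argmin of ``cv_rmse_``)
    """

    def __init__(
        self,
        property_tag: str = "MCA",
        hyperparameters: dict | None = None,
        n_estimators: int = 300,
        n_folds: int = 5,
        n_bins: int = 10,
        random_state: int = 0,
    ):
        self.property_tag = property_tag
        self.hyperparameters = hyperparameters
        self.n_estimators = n_estimators
        self.n_folds = n_folds
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y, fold_id=None):
        X = _check_features(X)
        y = np.asarray(y, dtype=float)
        if fold_id is None:
            assignment = SplitAssignment(
                bin_id=binned_split(y, n_bins=self.n_bins, seed=self.random_state).bin_id,
                partition=np.full(y.size, "train", dtype=object).astype(str),
                seed=self.random_state,
                n_bins=self.n_bins,
            )
            fold_id = stratified_folds(
                assignment, k=self.n_folds, seed=self.random_state
            )
        fold_id = np.asarray(fold_id)
        params = dict(self.hyperparameters or DEFAULT_HYPERPARAMETERS)
        self.models_ = []
        self.cv_rmse_ = []
        for f in range(self.n_folds):
            val = fold_id == f
            model = _lgbm(params, self.n_estimators, self.random_state)
            model.fit(X[~val], y[~val])
            pred = _silent_predict(model, X[val]) if val.any() else np.empty(0)
            rmse = _rmse(y[val], pred) if val.any() else float("inf")
            if not np.isfinite(rmse) and val.any():
                raise RuntimeError(f"non-finite validation loss in fold {f}")
            self.models_.append(model)
            self.cv_rmse_.append(rmse)
        self.best_fold_ = int(np.argmin(self.cv_rmse_))
        self.n_features_in_ = X.shape[1]
        self.data_hash_ = _data_hash(X, y)
        return self

    def predict(self, X):
        X = _check_features(X)
        if X.shape[0] == 0:
            return np.empty(0)
        return _silent_predict(self.models_[self.best_fold_], X)

    def fold_predictions(self, X) -> np.ndarray:
        """Predictions of all fold models, shape ``(n_folds, n_samples)``."""
        X = _check_features(X)
        if X.shape[0] == 0:
            return np.empty((self.n_folds, 0))
        return np.vstack([_silent_predict(m, X) for m in self.models_])


class ForestUncertainty(BaseEstimator):
    """Random-forest uncertainty: sigma = std over the 200 per-tree
    predictions (population std, ddof=0)."""

    method = "forest_std"

    def __init__(self, n_estimators: int = N_FOREST_TREES, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_features(X)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X, np.asarray(y, dtype=float))
        return self

    def tree_predictions(self, X) -> np.ndarray:
        """Per-tree predictions, shape ``(n_estimators, n_samples)``."""
        X = _check_features(X)
        return np.vstack([t.predict(X) for t in self.forest_.estimators_])

    def predict_std(self, X) -> np.ndarray:
        X = _check_features(X)
        if X.shape[0] == 0:
            return np.empty(0)
        return self.tree_predictions(X).std(axis=0, ddof=0)


class EnsembleUncertainty(BaseEstimator):
    """Uncertainty from the spread of the cross-validation fold models."""

    method = "ensemble_std"

    def __init__(self, regressor: AffinityRegressor | None = None):
        self.regressor = regressor

    def fit(self, X=None, y=None):
        if self.regressor is None or not hasattr(self.regressor, "models_"):
            raise ValueError("EnsembleUncertainty needs a fitted AffinityRegressor")
        return self

    def predict_std(self, X) -> np.ndarray:
        return self.regressor.fold_predictions(X).std(axis=0, ddof=0)


class KNNUncertainty(BaseEstimator):
    """Uncertainty proxy: mean distance to the k nearest training points."""

    method = "knn_dist"

    def __init__(self, k: int = 1, metric: str = "manhattan"):
        if metric not in ("manhattan", "euclidean"):
            raise ValueError(f"unsupported metric {metric!r}")
        self.k = k
        self.metric = metric

    def fit(self, X, y=None):
        X = _check_features(X)
        self.nn_ = NearestNeighbors(n_neighbors=self.k, metric=self.metric)
        self.nn_.fit(X)
        return self

    def predict_std(self, X) -> np.ndarray:
        X = _check_features(X)
        if X.shape[0] == 0:
            return np.empty(0)
        dist, _ = self.nn_.kneighbors(X)
        return dist.mean(axis=1)


# ---------------------------------------------------------------------------
# TPE-style hyperparameter search


def _to_unit(val, low, high, log):
    if log:
        return (np.log(val) - np.log(low)) / (np.log(high) - np.log(low))
    return (val - low) / (high - low)


def _from_unit(u, low, high, log, integer):
    u = float(np.clip(u, 0.0, 1.0))
    if log:
        val = np.exp(np.log(low) + u * (np.log(high) - np.log(low)))
    else:
        val = low + u * (high - low)
    if integer:
        val = int(round(val))
        val = int(np.clip(val, low, high))
    return val


def _parzen_logpdf(x: float, obs: np.ndarray) -> float:
    """Log density of a 1D Parzen mixture of unit-interval Gaussians."""
    bw = max(1.0 / max(len(obs), 1) ** 0.5 * 0.5, 1e-3)
    z = (x - obs) / bw
    return float(
        np.log(np.mean(np.exp(-0.5 * z**2)) / (bw * np.sqrt(2 * np.pi)) + 1e-300)
    )


def _sample_params(rng: np.random.Generator, space: dict) -> dict:
    return {
        name: _from_unit(rng.uniform(), lo, hi, log, integer)
        for name, (lo, hi, log, integer) in space.items()
    }


def _tpe_propose(
    rng: np.random.Generator,
    space: dict,
    history: list[tuple[dict, float]],
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> dict:
    order = sorted(range(len(history)), key=lambda i: history[i][1])
    n_good = max(1, int(np.ceil(gamma * len(history))))
    good_idx, bad_idx = order[:n_good], order[n_good:] or order[:1]
    unit_obs = {}
    for name, (lo, hi, log, _integer) in space.items():
        unit_obs[name] = (
            np.array([_to_unit(history[i][0][name], lo, hi, log) for i in good_idx]),
            np.array([_to_unit(history[i][0][name], lo, hi, log) for i in bad_idx]),
        )
    best_score, best = -np.inf, None
    for _ in range(n_candidates):
        cand_unit, score = {}, 0.0
        for name in space:
            good, bad = unit_obs[name]
            bw = max(1.0 / len(good) ** 0.5 * 0.5, 1e-3)
            u = float(np.clip(good[rng.integers(len(good))] + rng.normal(0, bw), 0, 1))
            cand_unit[name] = u
            score += _parzen_logpdf(u, good) - _parzen_logpdf(u, bad)
        if score > best_score:
            best_score, best = score, cand_unit
    return {
        name: _from_unit(best[name], lo, hi, log, integer)
        for name, (lo, hi, log, integer) in space.items()
    }


def tune_hyperparameters(
    X,
    y,
    fold_id,
    budget: int = 100,
    seed: int = 0,
    space: dict | None = None,
    n_estimators: int = 200,
) -> tuple[dict, float, list[float]]:
    """Seeded TPE-style Bayesian search minimising mean 5-fold CV RMSE.

    The first quarter of the budget (at most 10 trials) samples the space
    uniformly; subsequent trials split the history at the 25% objective
    quantile, model good and bad observations with per-dimension Parzen
    kernel densities, and keep the candidate maximising the good/bad
    density ratio.

    Returns ``(best_params, best_objective, best_so_far_trace)``.
    """
    if budget < 1:
        logger.warning("tuning budget < 1; returning default hyperparameters")
        return dict(DEFAULT_HYPERPARAMETERS), float("nan"), []
    space = space or DEFAULT_SEARCH_SPACE
    X = _check_features(X)
    y = np.asarray(y, dtype=float)
    fold_id = np.asarray(fold_id)
    folds = sorted(int(f) for f in np.unique(fold_id) if f >= 0)
    rng = np.random.default_rng(seed)
    n_startup = min(10, max(budget // 4, 1))

    def objective(params: dict) -> float:
        rmses = []
        for f in folds:
            val = fold_id == f
            m = _lgbm(params, n_estimators, seed)
            m.fit(X[~val], y[~val])
            rmses.append(_rmse(y[val], _silent_predict(m, X[val])))
        return float(np.mean(rmses))

    history: list[tuple[dict, float]] = []
    trace: list[float] = []
    for trial in range(budget):
        if trial < n_startup:
            params = _sample_params(rng, space)
        else:
            params = _tpe_propose(rng, space, history)
        value = objective(params)
        history.append((params, value))
        trace.append(min(value, trace[-1]) if trace else value)
    best_params, best_value = min(history, key=lambda t: t[1])
    return dict(best_params), float(best_value), trace


# ---------------------------------------------------------------------------
# functional wrappers


def train_regressor(
    X, y, fold_id, hyperparameters=None, seed: int = 0, property_tag: str = "MCA",
    n_estimators: int = 300,
) -> AffinityRegressor:
    """Fit an :class:`AffinityRegressor` on pre-assigned CV folds."""
    n_folds = len([f for f in np.unique(np.asarray(fold_id)) if f >= 0])
    reg = AffinityRegressor(
        property_tag=property_tag,
        hyperparameters=hyperparameters,
        n_folds=n_folds,
        random_state=seed,
        n_estimators=n_estimators,
    )
    return reg.fit(X, y, fold_id=fold_id)


def train_uncertainty(
    X, y, method: str = "forest_std", params: dict | None = None, seed: int = 0,
    regressor: AffinityRegressor | None = None,
):
    """Fit the requested uncertainty estimator."""
    params = params or {}
    if method == "forest_std":
        return ForestUncertainty(
            n_estimators=params.get("n_estimators", N_FOREST_TREES),
            random_state=seed,
        ).fit(X, y)
    if method == "ensemble_std":
        return EnsembleUncertainty(regressor=regressor).fit(X, y)
    if method == "knn_dist":
        return KNNUncertainty(
            k=params.get("k", 1), metric=params.get("metric", "manhattan")
        ).fit(X, y)
    raise ValueError(f"unknown uncertainty method {method!r}")


def predict(model: AffinityRegressor, unc, X) -> tuple[np.ndarray, np.ndarray]:
    """Point predictions (kJ/mol) and uncertainties for 53-dim descriptors."""
    X = _check_features(X)
    return model.predict(X), unc.predict_std(X)


# ---------------------------------------------------------------------------
# persistence


def save_bundle(path, regressor, uncertainty, calibrator=None, extra_meta=None):
    """Persist a trained model bundle (joblib artifact + JSON metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(
        {"regressor": regressor, "uncertainty": uncertainty, "calibrator": calibrator},
        path / "bundle.joblib",
    )
    meta = {
        "property": getattr(regressor, "property_tag", None),
        "cv_rmse": getattr(regressor, "cv_rmse_", None),
        "best_fold": getattr(regressor, "best_fold_", None),
        "data_hash": getattr(regressor, "data_hash_", None),
        "uncertainty_method": getattr(uncertainty, "method", None),
        "versions": {"lightgbm": lgb.__version__, "numpy": np.__version__},
    }
    if extra_meta:
        meta.update(extra_meta)
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    return path


def load_bundle(path) -> dict:
    path = Path(path)
    artifact = path / "bundle.joblib"
    if not artifact.exists():
        raise FileNotFoundError(f"missing model artifact: {artifact}")
    return joblib.load(artifact)
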