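"""Class-weighted boosted-tree training with Bayesian hyperparameter search.

Sample weights follow the inverse-frequency rule w_i = N / (K * n_c(i)),
which gives every class the same total weight (sum of all weights = N).
Three gradient-boosting backends share one fit/predict contract: XGBoost
(``xgb``), LightGBM (``lgbm``) and CatBoost (``cat``); the CatBoost search
space ships for completeness but fitting raises
:class:`~fallsense.errors.BackendUnavailableError` when the catboost
package is not installed.

Hyperparameter search spaces are frozen to the study's published ranges
(see ``SEARCH_SPACES``); ``PUBLISHED_OPTIMUM`` carries the published per-backend
optima as a ready-made preset.  The Bayesian optimizer is a small seeded
sequential model-based search: a Gaussian-process surrogate (Matern 5/2)
over the unit cube with expected-improvement acquisition, maximizing
validation macro-F1 of a weighted fit on an inner stratified split.
"""

from __future__ import annotations

import importlib.util
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from .errors import (BackendUnavailableError, ParameterError, RegistryError,
                     StratificationError, ValidationError)
from .features import FeatureMatrix

BACKENDS = ("xgb", "lgbm", "cat")


def compute_sample_weights(labels: np.ndarray | list[str]) -> np.ndarray:
    """Inverse-frequency weights w_i = N / (K * n_c(i)); sum(w) = N exactly."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValidationError("cannot weight an empty label vector")
    classes, counts = np.unique(labels, return_counts=True)
    n, k = labels.size, classes.size
    per_class = {c: n / (k * m) for c, m in zip(classes, counts)}
    return np.array([per_class[c] for c in labels], dtype=float)


# ---------------------------------------------------------------------------
# Search spaces (published ranges)

#: (scale, low, high); scale in {"uniform", "log-uniform", "integer-uniform"}.
SEARCH_SPACES: dict[str, dict[str, tuple[str, float, float]]] = {
    "xgb": {
        "learning_rate":    ("log-uniform", 0.005, 0.30),
        "n_estimators":     ("integer-uniform", 100, 800),
        "max_depth":        ("integer-uniform", 3, 10),
        "subsample":        ("uniform", 0.50, 1.00),
        "colsample_bytree": ("uniform", 0.30, 1.00),
        "gamma":            ("uniform", 0.0, 5.0),
        "min_child_weight": ("integer-uniform", 1, 10),
        "reg_alpha":        ("log-uniform", 1e-6, 10.0),
        "reg_lambda":       ("log-uniform", 1e-6, 10.0),
    },
    "lgbm": {
        "learning_rate":    ("log-uniform", 0.005, 0.30),
        "n_estimators":     ("integer-uniform", 100, 800),
        "max_depth":        ("integer-uniform", 3, 10),
        "subsample":        ("uniform", 0.50, 1.00),
        "colsample_bytree": ("uniform", 0.30, 1.00),
        "min_split_gain":   ("uniform", 0.0, 5.0),
        "min_child_weight": ("log-uniform", 1e-3, 10.0),
        "num_leaves":       ("integer-uniform", 15, 255),
        "reg_alpha":        ("log-uniform", 1e-6, 10.0),
        "reg_lambda":       ("log-uniform", 1e-6, 10.0),
    },
    "cat": {
        "learning_rate":       ("log-uniform", 0.005, 0.30),
        "iterations":          ("integer-uniform", 100, 800),
        "depth":               ("integer-uniform", 3, 10),
        "colsample_bylevel":   ("uniform", 0.30, 1.00),
        "bagging_temperature": ("uniform", 0.0, 1.0),
        "l2_leaf_reg":         ("log-uniform", 1e-3, 10.0),
    },
}

#: Published best configurations, usable as ``params="published-optimum"``.
PUBLISHED_OPTIMUM: dict[str, dict[str, float | int]] = {
    "xgb": {
        "learning_rate": 0.298, "n_estimators": 254, "max_depth": 9,
        "subsample": 0.959, "colsample_bytree": 0.948, "gamma": 0.036,
        "min_child_weight": 4, "reg_alpha": 0.006, "reg_lambda": 1.13e-5,
    },
    "lgbm": {
        "learning_rate": 0.020, "n_estimators": 760, "max_depth": 10,
        "subsample": 0.894, "colsample_bytree": 0.382, "min_split_gain": 0.919,
        "min_child_weight": 0.038, "num_leaves": 203,
        "reg_alpha": 0.030, "reg_lambda": 7.47e-4,
    },
    "cat": {
        "learning_rate": 0.092, "iterations": 539, "depth": 8,
        "colsample_bylevel": 0.892, "bagging_temperature": 0.657,
        "l2_leaf_reg": 1.146,
    },
}


def validate_params(backend: str, params: dict) -> None:
    """Reject hyperparameters outside the published search ranges."""
    space = _space_for(backend)
    for name, value in params.items():
        if name not in space:
            raise ValidationError(f"unknown {backend} hyperparameter {name!r}")
        scale, low, high = space[name]
        if not (low <= value <= high):
            raise ValidationError(
                f"{backend} hyperparameter {name}={value} outside [{low}, {high}]")
        if scale == "integer-uniform" and int(value) != value:
            raise ValidationError(f"{name} must be an integer, got {value}")


def _space_for(backend: str) -> dict[str, tuple[str, float, float]]:
    if backend not in SEARCH_SPACES:
        raise ValidationError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    return SEARCH_SPACES[backend]


def midpoint_params(backend: str) -> dict[str, float | int]:
    """The centre of every search dimension (geometric centre on log scales)."""
    out: dict[str, float | int] = {}
    for name, (scale, low, high) in _space_for(backend).items():
        if scale == "log-uniform":
            out[name] = float(np.sqrt(low * high))
        elif scale == "integer-uniform":
            out[name] = int(round((low + high) / 2))
        else:
            out[name] = (low + high) / 2
    return out


# ---------------------------------------------------------------------------
# Fitting and prediction


@dataclass
class TrainedModel:
    """A fitted multiclass booster plus everything needed to reuse it."""

    backend: str
    params: dict
    estimator: object = field(repr=False)
    registry: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int = 0
    weight_scheme: str = "inverse-frequency"

    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.registry if c not in X.columns]
        if missing:
            raise RegistryError(f"matrix lacks model features: {missing[:10]}")
        return X[list(self.registry)]

    def predict_proba(self, X: pd.DataFrame | FeatureMatrix) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.X
        proba = self.estimator.predict_proba(self._check_columns(X).to_numpy())
        return np.asarray(proba, dtype=float)

    def predict(self, X: pd.DataFrame | FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        """(labels, per-class scores); argmax with lowest-index tie-break."""
        proba = self.predict_proba(X)
        labels = np.array([self.classes[i] for i in proba.argmax(axis=1)],
                          dtype=object)
        return labels, proba

    def shap_values(self, X: pd.DataFrame | FeatureMatrix) -> np.ndarray:
        """Exact per-observation TreeSHAP contributions, shape (N, K, J).

        Computed by the boosters' built-in tree-path algorithm (no
        sampling); the bias column is dropped.
        """
        if isinstance(X, FeatureMatrix):
            X = X.X
        arr = self._check_columns(X).to_numpy()
        n, j = arr.shape
        k = len(self.classes)
        if self.backend == "xgb":
            import xgboost as xgb
            contribs = self.estimator.get_booster().predict(
                xgb.DMatrix(arr), pred_contribs=True)
            contribs = np.asarray(contribs)
            if contribs.ndim == 2:  # binary edge case
                contribs = contribs[:, None, :]
        elif self.backend == "lgbm":
            contribs = np.asarray(
                self.estimator.predict(arr, pred_contrib=True))
            contribs = contribs.reshape(n, k, j + 1)
        else:  # pragma: no cover - cat backend needs catboost
            raise BackendUnavailableError(
                "SHAP contributions for the 'cat' backend require catboost")
        return contribs[:, :, :j]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Native booster file plus a JSON sidecar with registry/params."""
        path = Path(path)
        if self.backend == "xgb":
            self.estimator.get_booster().save_model(str(path))
        elif self.backend == "lgbm":
            self.estimator.booster_.save_model(str(path))
        else:  # pragma: no cover
            raise BackendUnavailableError("cannot persist a 'cat' model")
        sidecar = {
            "backend": self.backend, "params": self.params,
            "registry": list(self.registry), "classes": list(self.classes),
            "seed": self.seed, "weight_scheme": self.weight_scheme,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        if meta["backend"] == "xgb":
            import xgboost as xgb
            est = xgb.XGBClassifier()
            est.load_model(str(path))
        elif meta["backend"] == "lgbm":
            import lightgbm as lgb
            booster = lgb.Booster(model_file=str(path))
            est = _LgbBoosterAdapter(booster)
        else:  # pragma: no cover
            raise BackendUnavailableError("cannot load a 'cat' model")
        return cls(backend=meta["backend"], params=meta["params"], estimator=est,
                   registry=tuple(meta["registry"]), classes=tuple(meta["classes"]),
                   seed=meta["seed"], weight_scheme=meta["weight_scheme"])


class _LgbBoosterAdapter:
    """predict_proba/predict facade over a bare LightGBM Booster."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, X):
        return self.booster.predict(X)

    def predict(self, X, **kw):
        return self.booster.predict(X, **kw)


def _class_order(y: np.ndarray) -> tuple[str, ...]:
    from .io import CLASSES
    present = set(y)
    ordered = [c for c in CLASSES if c in present]
    ordered += sorted(present - set(CLASSES))
    return tuple(ordered)


def fit(backend: str, train: FeatureMatrix, weights: np.ndarray | None = None,
        params: dict | str | None = None, seed: int = 0) -> TrainedModel:
    """Fit one weighted multiclass booster.

    ``params`` may be a dict (validated against the search range), the
    string ``"published-optimum"``, or None for the published optimum of the
    backend.  ``weights=None`` applies the inverse-frequency rule.
    """
    if backend not in BACKENDS:
        raise ValidationError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    if backend == "cat" and importlib.util.find_spec("catboost") is None:
        raise BackendUnavailableError(
            "backend 'cat' requires the catboost package, which is not installed")
    if params is None or params == "published-optimum":
        params = dict(PUBLISHED_OPTIMUM[backend])
    else:
        params = dict(params)
        validate_params(backend, params)
    if weights is None:
        weights = compute_sample_weights(train.y)
    if len(weights) != train.N:
        raise ValidationError("weights length must equal the number of rows")

    classes = _class_order(train.y)
    y_int = np.array([classes.index(c) for c in train.y])
    Xarr = train.X.to_numpy()

    if backend == "xgb":
        import xgboost as xgb
        est = xgb.XGBClassifier(
            objective="multi:softprob", tree_method="hist",
            n_jobs=1, random_state=seed, verbosity=0, **params)
        est.fit(Xarr, y_int, sample_weight=weights)
    elif backend == "lgbm":
        import lightgbm as lgb
        est = lgb.LGBMClassifier(
            objective="multiclass", n_jobs=1, random_state=seed,
            deterministic=True, force_row_wise=True, verbose=-1,
            subsample_freq=1, **params)
        est.fit(Xarr, y_int, sample_weight=weights)
    else:  # pragma: no cover - requires catboost
        import catboost
        est = catboost.CatBoostClassifier(
            loss_function="MultiClass", random_seed=seed, verbose=False, **params)
        est.fit(Xarr, y_int, sample_weight=weights)

    return TrainedModel(backend=backend, params=params, estimator=est,
                        registry=train.registry, classes=classes, seed=seed)


def predict(model: TrainedModel,
            matrix: FeatureMatrix | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Module-level alias of :meth:`TrainedModel.predict`."""
    return model.predict(matrix)


# ---------------------------------------------------------------------------
# Bayesian optimization (sequential model-based search)


def _to_unit(space: dict, params: dict) -> np.ndarray:
    u = []
    for name, (scale, low, high) in space.items():
        v = params[name]
        if scale == "log-uniform":
            u.append((np.log(v) - np.log(low)) / (np.log(high) - np.log(low)))
        else:
            u.append((v - low) / (high - low))
    return np.clip(np.array(u), 0.0, 1.0)


def _from_unit(space: dict, u: np.ndarray) -> dict:
    params = {}
    for (name, (scale, low, high)), x in zip(space.items(), u):
        if scale == "log-uniform":
            params[name] = float(np.exp(np.log(low) + x * (np.log(high) - np.log(low))))
        elif scale == "integer-uniform":
            params[name] = int(round(low + x * (high - low)))
        else:
            params[name] = float(low + x * (high - low))
    return params


def bayes_optimize(train: FeatureMatrix, backend: str = "xgb",
                   n_trials: int = 50, inner_fraction: float = 0.2,
                   seed: int = 0) -> tuple[dict, list[dict]]:
    """Maximize inner-validation macro-F1 over the backend's search space.

    An inner stratified split of ``train`` provides the validation part;
    every candidate is fitted with inverse-frequency weights on the inner
    training part.  The first min(10, n_trials) candidates are random;
    later ones maximize expected improvement under a Gaussian-process
    surrogate.  Deterministic under ``seed``.  Returns (best parameters,
    full trial log).
    """
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    space = _space_for(backend)
    counts = train.n_c
    if min(counts.values()) < 2 or len(counts) < 2:
        raise StratificationError(
            f"need >= 2 classes with >= 2 rows each for the inner split, got {counts}")
    idx = np.arange(train.N)
    tr_idx, va_idx = train_test_split(
        idx, test_size=inner_fraction, stratify=train.y,
        random_state=seed % (2 ** 31))
    inner_tr, inner_va = train.rows(tr_idx), train.rows(va_idx)
    weights = compute_sample_weights(inner_tr.y)

    def objective(params: dict) -> float:
        model = fit(backend, inner_tr, weights=weights, params=params, seed=seed)
        labels, _ = model.predict(inner_va)
        return float(f1_score(inner_va.y, labels, average="macro", zero_division=0))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA7E5]))
    dim = len(space)
    n_init = min(10, n_trials)
    points: list[np.ndarray] = []
    scores: list[float] = []
    log: list[dict] = []

    for trial in range(n_trials):
        if trial < n_init:
            u = rng.uniform(size=dim)
        else:
            u = _propose_ei(np.array(points), np.array(scores), rng, dim)
        params = _from_unit(space, u)
        score = objective(params)
        points.append(_to_unit(space, params))
        scores.append(score)
        log.append({"trial": trial, "params": params, "macro_f1": score})

    best = int(np.argmax(scores))
    return log[best]["params"], log


def _propose_ei(points: np.ndarray, scores: np.ndarray,
                rng: np.random.Generator, dim: int,
                n_candidates: int = 256) -> np.ndarray:
    """Expected-improvement maximizer over random candidates under a GP."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=np.full(dim, 0.3),
                       length_scale_bounds=(1e-2, 1e2), nu=2.5)
              + WhiteKernel(1e-6, (1e-9, 1e-1)))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  n_restarts_optimizer=0, random_state=0)
    gp.fit(points, scores)
    cand = rng.uniform(size=(n_candidates, dim))
    mu, sigma = gp.predict(cand, return_std=True)
    best = scores.max()
    sigma = np.maximum(sigma, 1e-9)
    z = (mu - best) / sigma
    ei = (mu - best) * sps.norm.cdf(z) + sigma * sps.norm.pdf(z)
    return cand[int(np.argmax(ei))]
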