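"""Ensemble feature selection: SHAP-Select + permutation importance.

SHAP-Select regresses the true class labels on the per-feature SHAP
contributions of a fitted tree model: with K classes the linear predictor
for observation i and class k is eta_ik = sum_j beta_j * phi_ijk (one
shared coefficient per feature across the class logits), with a softmax
likelihood.  A feature is kept in ``significant`` mode when its
coefficient is positive and Wald-significant after Bonferroni correction
(p < alpha / J); ``nonnegative`` mode keeps everything that is not
significantly negative.

Permutation feature importance (PFI) shuffles one validation column at a
time and records the macro-F1 drop; a feature is retained when its mean
drop over R repeats is strictly positive.

The ensemble set is the exact union of the two selections: statistical
robustness (SHAP-Select) or empirical impact (PFI) suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from sklearn.metrics import f1_score

from .errors import RegistryError, StratificationError, ValidationError
from .features import FeatureMatrix
from .training import TrainedModel

#: Ridge penalty stabilizing the SHAP regression's maximum-likelihood fit.
SHAP_RIDGE = 1e-6
#: Escalation ladder used when the fit fails to converge or the likelihood
#: saturates (complete separation, under which Wald inference is undefined);
#: an escalated ridge is flagged in the diagnostics.
SHAP_RIDGE_LADDER = (1e-2, 1.0)
#: Mean top-class probability above which the fit counts as saturated.
SHAP_SATURATION = 0.999


@dataclass
class ShapRegressionResult:
    """Per-feature coefficients, Wald p-values and Bonferroni decisions."""

    table: pd.DataFrame  # feature, beta, se, z, p_value, decision
    alpha: float
    bonferroni_threshold: float
    converged: bool
    ridge: float
    ridge_fallback: bool = False

    def decided(self, decision: str) -> list[str]:
        return list(self.table.loc[self.table["decision"] == decision, "feature"])


@dataclass
class PfiResult:
    """Per-feature macro-F1 drops over R permutations."""

    table: pd.DataFrame  # feature, mean_drop, retained
    drops: np.ndarray = field(repr=False)  # (J, R)
    baseline: float = 0.0
    repeats: int = 0

    @property
    def retained(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "feature"])


@dataclass
class SelectionResult:
    """The three selected sets plus full diagnostics.

    ``ensemble`` is always the exact union of the SHAP and PFI sets;
    ``selected`` is the set the final model is refitted on (the
    mode-dependent choice, falling back to the full registry if a
    degenerate selection came back empty).
    """

    shap_selected: tuple[str, ...]
    pfi_selected: tuple[str, ...]
    ensemble: tuple[str, ...]
    selected: tuple[str, ...]
    shap_result: ShapRegressionResult | None = None
    pfi_result: PfiResult | None = None
    mode: str = "ensemble"


def _softmax(eta: np.ndarray) -> np.ndarray:
    eta = eta - eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def _fit_shap_regression(phi: np.ndarray, y_onehot: np.ndarray,
                         ridge: float) -> tuple[np.ndarray, bool]:
    """Maximize the shared-coefficient softmax likelihood with L-BFGS."""
    n, k, j = phi.shape

    def nll_grad(beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = np.einsum("nkj,j->nk", phi, beta)
        eta_max = eta.max(axis=1)
        lse = eta_max + np.log(np.exp(eta - eta_max[:, None]).sum(axis=1))
        nll = float((lse - (eta * y_onehot).sum(axis=1)).sum()
                    + ridge * (beta ** 2).sum())
        p = _softmax(eta)
        grad = np.einsum("nk,nkj->j", p - y_onehot, phi) + 2.0 * ridge * beta
        return nll, grad

    res = optimize.minimize(nll_grad, np.zeros(j), jac=True, method="L-BFGS-B",
                            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8})
    return res.x, bool(res.success)


def _wald_table(phi: np.ndarray, y_onehot: np.ndarray, beta: np.ndarray,
                ridge: float, names: list[str], alpha: float) -> pd.DataFrame:
    """Wald z/p per coefficient from the penalized observed information."""
    p = _softmax(np.einsum("nkj,j->nk", phi, beta))
    h = np.einsum("nk,nkj,nkl->jl", p, phi, phi)
    a = np.einsum("nk,nkj->nj", p, phi)
    h -= np.einsum("nj,nl->jl", a, a)
    h += 2.0 * ridge * np.eye(len(beta))
    cov = np.linalg.pinv(h)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * sps.norm.sf(np.abs(z))
    threshold = alpha / len(names)
    decision = np.where(
        (pval < threshold) & (beta > 0), "significant_positive",
        np.where((pval < threshold) & (beta < 0), "significant_negative",
                 "nonsignificant"))
    return pd.DataFrame({"feature": names, "beta": beta, "se": se, "z": z,
                         "p_value": pval, "decision": decision})


def shap_select(model: TrainedModel, val: FeatureMatrix,
                mode: str = "significant",
                alpha: float = 0.05) -> tuple[list[str], ShapRegressionResult]:
    """SHAP-Select on the validation set; returns (feature names, diagnostics)."""
    if mode not in ("significant", "nonnegative"):
        raise ValidationError(f"unknown SHAP-Select mode {mode!r}")
    if len(set(val.y)) < 2:
        raise StratificationError(
            "SHAP-Select needs a validation set with >= 2 classes")
    phi = model.shap_values(val)  # (N, K, J)
    names = list(model.registry)
    k = len(model.classes)
    y_onehot = np.zeros((val.N, k))
    for i, label in enumerate(val.y):
        y_onehot[i, model.classes.index(label)] = 1.0

    fallback = False
    for ridge in (SHAP_RIDGE, *SHAP_RIDGE_LADDER):
        beta, ok = _fit_shap_regression(phi, y_onehot, ridge)
        p_hat = _softmax(np.einsum("nkj,j->nk", phi, beta))
        saturated = float(p_hat.max(axis=1).mean()) > SHAP_SATURATION
        if ok and not saturated:
            break
        fallback = True
    table = _wald_table(phi, y_onehot, beta, ridge, names, alpha)
    result = ShapRegressionResult(
        table=table, alpha=alpha, bonferroni_threshold=alpha / len(names),
        converged=ok, ridge=ridge, ridge_fallback=fallback)
    if mode == "significant":
        selected = result.decided("significant_positive")
    else:
        selected = [f for f in names
                    if f not in set(result.decided("significant_negative"))]
    return selected, result


def permutation_importance(model: TrainedModel, val: FeatureMatrix,
                           repeats: int = 10, seed: int = 0) -> PfiResult:
    """Mean macro-F1 drop per feature over R seeded column permutations."""
    if repeats < 1:
        raise ValidationError(f"repeats must be >= 1, got {repeats}")
    names = list(model.registry)
    Xv = val.X[names].to_numpy().copy()
    truth = val.y

    def score(arr: np.ndarray) -> float:
        proba = model.estimator.predict_proba(arr)
        labels = np.array([model.classes[i] for i in np.asarray(proba).argmax(1)],
                          dtype=object)
        return float(f1_score(truth, labels, average="macro", zero_division=0))

    baseline = score(Xv)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9F1]))
    drops = np.zeros((len(names), repeats))
    for j in range(len(names)):
        original = Xv[:, j].copy()
        for r in range(repeats):
            perm = rng.permutation(len(Xv))
            permuted = original[perm]
            if np.array_equal(permuted, original):
                drops[j, r] = 0.0  # permutation of a constant is the identity
                continue
            Xv[:, j] = permuted
            drops[j, r] = baseline - score(Xv)
        Xv[:, j] = original
    mean_drop = drops.mean(axis=1)
    table = pd.DataFrame({"feature": names, "mean_drop": mean_drop,
                          "retained": mean_drop > 0})
    return PfiResult(table=table, drops=drops, baseline=baseline, repeats=repeats)


def ensemble_select(shap_set: list[str] | tuple[str, ...],
                    pfi_set: list[str] | tuple[str, ...],
                    registry: tuple[str, ...]) -> tuple[str, ...]:
    """Exact set union, returned in stable registry order."""
    known = set(registry)
    for name in list(shap_set) + list(pfi_set):
        if name not in known:
            raise RegistryError(f"feature {name!r} not in the registry")
    union = set(shap_set) | set(pfi_set)
    return tuple(f for f in registry if f in union)


def select_features(model: TrainedModel, val: FeatureMatrix,
                    mode: str = "ensemble", alpha: float = 0.05,
                    pfi_repeats: int = 10, seed: int = 0) -> SelectionResult:
    """Run the requested selection strategy and package the diagnostics."""
    if mode not in ("ensemble", "shap", "shap-nonnegative", "pfi", "none"):
        raise ValidationError(f"unknown selection mode {mode!r}")
    registry = model.registry
    if mode == "none":
        return SelectionResult(registry, registry, registry, registry, mode=mode)
    shap_sel: list[str] = []
    pfi_sel: list[str] = []
    shap_res = pfi_res = None
    if mode in ("ensemble", "shap", "shap-nonnegative"):
        shap_mode = "nonnegative" if mode == "shap-nonnegative" else "significant"
        shap_sel, shap_res = shap_select(model, val, mode=shap_mode, alpha=alpha)
    if mode in ("ensemble", "pfi"):
        pfi_res = permutation_importance(model, val, repeats=pfi_repeats, seed=seed)
        pfi_sel = pfi_res.retained
    union = ensemble_select(shap_sel, pfi_sel, registry)
    if mode == "ensemble":
        chosen = union
    elif mode in ("shap", "shap-nonnegative"):
        chosen = tuple(f for f in registry if f in set(shap_sel))
    else:
        chosen = tuple(f for f in registry if f in set(pfi_sel))
    if not chosen:
        # degenerate guard: an empty feature set cannot be refitted
        chosen = registry
    return SelectionResult(
        shap_selected=tuple(f for f in registry if f in set(shap_sel)),
        pfi_selected=tuple(f for f in registry if f in set(pfi_sel)),
        ensemble=union, selected=chosen,
        shap_result=shap_res, pfi_result=pfi_res, mode=mode)
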