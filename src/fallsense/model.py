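"""Model/Results facade over the detection pipeline.

`FallDetectionModel` is built from data (labeled windows, recordings, or a
ready feature matrix); its :meth:`fit` runs weighting, optional Bayesian
hyperparameter search, optional SHAP+PFI feature selection, and the final
weighted boosted-tree fit, returning a :class:`FallDetectionResults`
carrying the fitted booster, the selection diagnostics, and a
``summary()`` table.

Example
-------
>>> from fallsense import synthetic, model
>>> recs = synthetic.generate_dataset(synthetic.GeneratorSpec.balanced(60, 16, 8))
>>> res = model.FallDetectionModel.from_recordings(recs).fit(seed=0)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evaluation import EvaluationReport, confusion, cross_validate, macro_metrics
from .features import FeatureMatrix, build_matrix
from .io import ImuRecording
from .preprocessing import LabeledWindow, preprocess_recording
from .selection import SelectionResult, select_features
from .training import TrainedModel, bayes_optimize, compute_sample_weights, fit


class FallDetectionModel:
    """Pre-impact fall classifier specification bound to training data."""

    def __init__(self, features: FeatureMatrix,
                 windows: list[LabeledWindow] | None = None):
        if features.N < 10:
            raise ValidationError("need at least 10 training rows")
        self.features = features
        self.windows = windows

    @classmethod
    def from_windows(cls, windows: list[LabeledWindow]) -> "FallDetectionModel":
        return cls(build_matrix(windows), windows=windows)

    @classmethod
    def from_recordings(cls, recordings: list[ImuRecording], stride: int = 40,
                        kernel: int = 5) -> "FallDetectionModel":
        windows: list[LabeledWindow] = []
        for rec in recordings:
            windows.extend(preprocess_recording(rec, stride=stride, kernel=kernel))
        return cls.from_windows(windows)

    def fit(self, backend: str = "xgb", params: dict | str | None = "published-optimum",
            n_trials: int = 0, selection: str = "none", alpha: float = 0.05,
            pfi_repeats: int = 10, val_fraction: float = 0.2,
            seed: int = 0) -> "FallDetectionResults":
        """Fit the weighted booster; optionally search and select first.

        ``selection`` is one of none/shap/shap-nonnegative/pfi/ensemble;
        with ``n_trials > 0`` a Bayesian search replaces ``params``.
        """
        fm = self.features
        if n_trials > 0:
            params, trial_log = bayes_optimize(fm, backend=backend,
                                               n_trials=n_trials, seed=seed)
        else:
            trial_log = []

        sel: SelectionResult | None = None
        use = fm.registry
        if selection != "none":
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFACE]))
            order = rng.permutation(fm.N)
            n_val = max(fm.K, int(round(val_fraction * fm.N)))
            inner_fit = fm.rows(order[n_val:])
            inner_val = fm.rows(order[:n_val])
            base = fit(backend, inner_fit, params=params, seed=seed)
            sel = select_features(base, inner_val, mode=selection, alpha=alpha,
                                  pfi_repeats=pfi_repeats, seed=seed)
            use = sel.selected

        final = fit(backend, fm.subset(use), params=params, seed=seed)
        train_pred, _ = final.predict(fm.subset(use))
        train_mm = macro_metrics(confusion(fm.y, train_pred, classes=final.classes))
        return FallDetectionResults(self, final, selection=sel,
                                    trial_log=trial_log, train_metrics=train_mm,
                                    seed=seed)

    def cross_validate(self, k: int = 5, seed: int = 0,
                       **kwargs) -> EvaluationReport:
        if self.windows is None:
            raise ValidationError(
                "cross_validate needs the model built from windows/recordings")
        return cross_validate(self.windows, k=k, seed=seed, **kwargs)


class FallDetectionResults:
    """Fitted classifier plus diagnostics, in the Results-object idiom."""

    def __init__(self, model: FallDetectionModel, trained: TrainedModel,
                 selection: SelectionResult | None, trial_log: list[dict],
                 train_metrics, seed: int):
        self.model = model
        self.trained = trained
        self.selection = selection
        self.trial_log = trial_log
        self.train_metrics = train_metrics
        self.seed = seed

    # -- estimates ----------------------------------------------------------

    @property
    def features_used(self) -> tuple[str, ...]:
        return self.trained.registry

    @property
    def params(self) -> dict:
        return self.trained.params

    @property
    def sample_weights(self) -> np.ndarray:
        return compute_sample_weights(self.model.features.y)

    def feature_table(self) -> pd.DataFrame:
        """Per-feature selection statistics (beta, p, PFI drop, membership)."""
        registry = self.model.features.registry
        table = pd.DataFrame({"feature": list(registry)})
        table["used"] = table.feature.isin(self.features_used)
        if self.selection is not None:
            if self.selection.shap_result is not None:
                shap_t = self.selection.shap_result.table
                table = table.merge(
                    shap_t[["feature", "beta", "p_value", "decision"]],
                    on="feature", how="left")
                table["shap_selected"] = table.feature.isin(
                    self.selection.shap_selected)
            if self.selection.pfi_result is not None:
                table = table.merge(
                    self.selection.pfi_result.table[["feature", "mean_drop"]],
                    on="feature", how="left")
                table["pfi_selected"] = table.feature.isin(
                    self.selection.pfi_selected)
        return table

    # -- prediction ---------------------------------------------------------

    def predict(self, X: pd.DataFrame | FeatureMatrix) -> np.ndarray:
        return self.trained.predict(X)[0]

    def predict_proba(self, X: pd.DataFrame | FeatureMatrix) -> np.ndarray:
        return self.trained.predict_proba(X)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        fm = self.model.features
        lines = [
            "Pre-impact fall detection results",
            "=" * 48,
            f"backend:            {self.trained.backend}",
            f"training rows:      {fm.N}",
            f"class counts:       " + ", ".join(
                f"{c}={fm.n_c.get(c, 0)}" for c in fm.classes),
            f"weight scheme:      inverse frequency, sum(w) = N = {fm.N}",
            f"features used:      {len(self.features_used)} / {len(fm.registry)}",
        ]
        if self.selection is not None:
            lines += [
                f"selection mode:     {self.selection.mode}",
                f"  SHAP-selected:    {len(self.selection.shap_selected)}",
                f"  PFI-selected:     {len(self.selection.pfi_selected)}",
                f"  ensemble union:   {len(self.selection.ensemble)}",
            ]
        if self.trial_log:
            best = max(t["macro_f1"] for t in self.trial_log)
            lines.append(f"search trials:      {len(self.trial_log)} "
                         f"(best inner macro-F1 {best:.3f})")
        lines.append("hyperparameters:")
        for k, v in sorted(self.params.items()):
            lines.append(f"  {k:20s} {v}")
        tm = self.train_metrics
        lines += [
            "training-set macro metrics:",
            f"  accuracy={tm.accuracy:.4f}  sensitivity={tm.sensitivity:.4f}  "
            f"specificity={tm.specificity:.4f}",
            f"  F1={tm.f1:.4f}  MCC={tm.mcc:.4f}",
        ]
        return "\n".join(lines)
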