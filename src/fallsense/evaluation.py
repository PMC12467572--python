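"""Evaluation: macro metrics, PR-AUC, cross-validation, lead time, latency.

All macro metrics are one-vs-rest per-class quantities averaged with equal
class weight:

    F1_macro   = (1/K) sum_k 2 TP_k / (2 TP_k + FP_k + FN_k)
    Acc_macro  = (1/K) sum_k (TP_k + TN_k) / (TP_k + TN_k + FP_k + FN_k)
    Sens_macro = (1/K) sum_k TP_k / (TP_k + FN_k)
    Spec_macro = (1/K) sum_k TN_k / (TN_k + FP_k)
    MCC_macro  = (1/K) sum_k binary MCC of class k

A per-class term with a zero denominator contributes 0 to the average
(degenerate folds).  PR-AUC is average precision (step-function
integration, no interpolation), the conservative choice under class
imbalance.

Lead time is the interval from detection activation to impact onset.  The
detection replay slides a stride-1 window over a test recording, scores
every window ending before the impact, and fires on the first window
predicted as a fall class; lead time is measured from that window's last
sample to the impact.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .errors import StratificationError, ValidationError
from .features import FeatureMatrix, build_matrix, extract_feature_frame
from .io import CLASSES, FALL_CLASSES, ImuRecording
from .preprocessing import LabeledWindow, augment, segment_windows
from .selection import SelectionResult, select_features
from .training import TrainedModel, bayes_optimize, compute_sample_weights, fit

#: Published wearable-airbag inflation time the lead time must exceed (ms).
AIRBAG_INFLATION_MS = 130.0


# ---------------------------------------------------------------------------
# Confusion counts and macro metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tallies per class."""

    classes: tuple[str, ...]
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


def confusion(y_true: np.ndarray | list[str],
              y_pred: np.ndarray | list[str],
              classes: tuple[str, ...] | None = None) -> ConfusionCounts:
    """One-vs-rest confusion tallies for every class."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise ValidationError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted")
    if classes is None:
        present = set(y_true) | set(y_pred)
        classes = tuple([c for c in CLASSES if c in present]
                        + sorted(present - set(CLASSES)))
    tp, fp, tn, fn = (np.zeros(len(classes), dtype=int) for _ in range(4))
    for i, c in enumerate(classes):
        is_c = y_true == c
        pred_c = y_pred == c
        tp[i] = np.count_nonzero(is_c & pred_c)
        fp[i] = np.count_nonzero(~is_c & pred_c)
        fn[i] = np.count_nonzero(is_c & ~pred_c)
        tn[i] = np.count_nonzero(~is_c & ~pred_c)
    return ConfusionCounts(classes=classes, tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with zero-denominator terms contributing 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


@dataclass(frozen=True)
class MacroMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1, "mcc": self.mcc}


def macro_metrics(cc: ConfusionCounts) -> MacroMetrics:
    """Macro accuracy/sensitivity/specificity/F1/MCC from one-vs-rest counts."""
    tp, fp, tn, fn = (a.astype(float) for a in (cc.tp, cc.fp, cc.tn, cc.fn))
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    return MacroMetrics(accuracy=float(acc.mean()), sensitivity=float(sens.mean()),
                        specificity=float(spec.mean()), f1=float(f1.mean()),
                        mcc=float(mcc.mean()))


def pr_auc_per_class(y_true: np.ndarray | list[str], scores: np.ndarray,
                     classes: tuple[str, ...]) -> dict[str, float | None]:
    """One-vs-rest average precision per class; absent classes report None."""
    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (y_true.size, len(classes)):
        raise ValidationError(
            f"scores must be {(y_true.size, len(classes))}, got {scores.shape}")
    out: dict[str, float | None] = {}
    for i, c in enumerate(classes):
        positives = y_true == c
        if not positives.any():
            out[c] = None
            continue
        out[c] = float(average_precision_score(positives, scores[:, i]))
    return out


# ---------------------------------------------------------------------------
# Lead time and detection replay


def lead_time(detection_end_time: float, impact_t: float) -> float:
    """Milliseconds from detection activation to impact onset."""
    if not detection_end_time < impact_t:
        raise ValidationError(
            f"detection at {detection_end_time} s is not before impact {impact_t} s")
    return (impact_t - detection_end_time) * 1000.0


@dataclass(frozen=True)
class DetectionOutcome:
    recording_id: str
    true_class: str
    detected: bool
    predicted_class: str | None = None
    detection_time: float | None = None
    lead_time_ms: float | None = None


def replay_detection(model: TrainedModel, rec: ImuRecording, kernel: int = 5,
                     vote: int = 1) -> DetectionOutcome:
    """Online detection replay with stride-1 sliding windows.

    Fires on the first run of ``vote`` consecutive windows predicted as a
    fall class.  For fall recordings only windows ending before the impact
    participate; a fall with no firing is a missed detection.
    """
    ann = rec.annotation
    windows = segment_windows(rec, stride=1, kernel=kernel)
    if ann.is_fall:
        windows = [w for w in windows if w.end_time < ann.impact_t]
    if not windows:
        return DetectionOutcome(rec.recording_id, ann.klass, detected=False)
    frame = extract_feature_frame(windows)
    labels, _ = model.predict(frame[list(model.registry)])
    is_fall_pred = np.isin(labels, FALL_CLASSES)
    run = 0
    for i, flag in enumerate(is_fall_pred):
        run = run + 1 if flag else 0
        if run >= vote:
            w = windows[i]
            lt = (lead_time(w.end_time, ann.impact_t)
                  if ann.is_fall else None)
            return DetectionOutcome(
                rec.recording_id, ann.klass, detected=True,
                predicted_class=str(labels[i]), detection_time=w.end_time,
                lead_time_ms=lt)
    return DetectionOutcome(rec.recording_id, ann.klass, detected=False)


def lead_time_summary(model: TrainedModel, recordings: list[ImuRecording],
                      kernel: int = 5, vote: int = 1) -> dict:
    """Mean/std lead time per fall class over first-detection replays.

    Missed detections (no firing before impact) are counted separately and
    excluded from the mean.  Non-fall recordings contribute to the
    false-alarm count instead.
    """
    leads: dict[str, list[float]] = {c: [] for c in FALL_CLASSES}
    missed = {c: 0 for c in FALL_CLASSES}
    false_alarms = 0
    n_non_fall = 0
    outcomes = []
    for rec in recordings:
        outcome = replay_detection(model, rec, kernel=kernel, vote=vote)
        outcomes.append(outcome)
        klass = rec.annotation.klass
        if klass in FALL_CLASSES:
            if outcome.detected:
                leads[klass].append(outcome.lead_time_ms)
            else:
                missed[klass] += 1
        else:
            n_non_fall += 1
            if outcome.detected:
                false_alarms += 1
    summary = {}
    for c in FALL_CLASSES:
        vals = np.array(leads[c])
        summary[c] = {
            "n_detected": int(vals.size),
            "n_missed": missed[c],
            "mean_lead_ms": float(vals.mean()) if vals.size else None,
            "std_lead_ms": float(vals.std()) if vals.size else None,
            "min_lead_ms": float(vals.min()) if vals.size else None,
        }
    summary["false_alarms"] = false_alarms
    summary["n_non_fall_replayed"] = n_non_fall
    return summary


def measure_latency(model: TrainedModel, windows_frame: pd.DataFrame,
                    warmup: int = 10) -> dict:
    """Wall-clock scoring cost in ms per window, with host metadata.

    Report-only: hardware-dependent, never a comparison target.
    """
    if len(windows_frame) < 100:
        raise ValidationError("latency measurement needs >= 100 windows")
    arr = windows_frame[list(model.registry)]
    for _ in range(warmup):
        model.predict(arr.iloc[:1])
    start = time.perf_counter()
    model.predict(arr)
    elapsed = time.perf_counter() - start
    return {
        "ms_per_window": elapsed * 1000.0 / len(arr),
        "n_windows": len(arr),
        "host": {"machine": platform.machine(), "processor": platform.processor(),
                 "python": platform.python_version(), "system": platform.system()},
    }


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class EvaluationReport:
    """Per-fold macro metrics and PR-AUC plus aggregate mean +/- std."""

    folds: list[dict]
    aggregate: dict[str, dict[str, float]]
    n_selected: list[int] = field(default_factory=list)
    params: dict | None = None
    backend: str = "xgb"

    def to_dict(self) -> dict:
        return {"backend": self.backend, "params": self.params,
                "folds": self.folds, "aggregate": self.aggregate,
                "n_selected_per_fold": self.n_selected}


def cross_validate(windows: list[LabeledWindow], k: int = 5,
                   backend: str = "xgb", params: dict | str | None = None,
                   n_trials: int = 0, selection_mode: str = "none",
                   alpha: float = 0.05, pfi_repeats: int = 10,
                   augment_level: int | None = 2, val_fraction: float = 0.2,
                   feature_subset: tuple[str, ...] | None = None,
                   seed: int = 0) -> EvaluationReport:
    """Stratified k-fold CV with per-fold augmentation (and optionally
    per-fold selection).

    Augmentation and any feature selection are fitted on each fold's
    training portion only; the held-out fold stays untouched (no leakage).
    When ``n_trials > 0`` the hyperparameter search runs once on the first
    fold's training portion and the winning configuration is reused for
    every fold.  ``feature_subset`` restricts every fold to a fixed,
    externally selected feature set (the subset-ablation protocol).
    """
    originals = [w for w in windows if w.origin == "real"]
    labels = np.array([w.label for w in originals], dtype=object)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"every class needs >= {k} windows for {k}-fold CV; got "
            f"{dict(zip(classes, counts))}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    folds_out: list[dict] = []
    n_selected: list[int] = []
    chosen_params = params

    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(labels, labels)):
        train_w = [originals[i] for i in tr_idx]
        test_w = [originals[i] for i in te_idx]
        if augment_level is not None:
            train_w = augment(train_w, level=augment_level,
                              seed=seed * 1000 + fold_i)
        train_m = build_matrix(train_w)
        test_m = build_matrix(test_w)
        if feature_subset is not None:
            train_m = train_m.subset(feature_subset)
            test_m = test_m.subset(feature_subset)

        if fold_i == 0 and n_trials > 0 and chosen_params in (None, "search"):
            chosen_params, _ = bayes_optimize(
                train_m, backend=backend, n_trials=n_trials, seed=seed)

        # inner split for selection's validation set
        if selection_mode != "none":
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), fold_i, 0x5E1]))
            order = rng.permutation(train_m.N)
            n_val = max(len(set(train_m.y)), int(round(val_fraction * train_m.N)))
            va_idx, fit_idx = order[:n_val], order[n_val:]
            inner_fit, inner_val = train_m.rows(fit_idx), train_m.rows(va_idx)
            base = fit(backend, inner_fit, params=chosen_params, seed=seed)
            sel = select_features(base, inner_val, mode=selection_mode,
                                  alpha=alpha, pfi_repeats=pfi_repeats, seed=seed)
            use = sel.selected
        else:
            use = train_m.registry
        n_selected.append(len(use))

        model = fit(backend, train_m.subset(use), params=chosen_params, seed=seed)
        pred, proba = model.predict(test_m.subset(use))
        mm = macro_metrics(confusion(test_m.y, pred, classes=model.classes))
        pr = pr_auc_per_class(test_m.y, proba, model.classes)
        folds_out.append({
            "fold": fold_i,
            **{f"macro_{k_}": v for k_, v in mm.as_dict().items()},
            **{f"pr_auc_{c}": pr[c] for c in model.classes},
        })

    keys = [k_ for k_ in folds_out[0] if k_ != "fold"]
    aggregate = {}
    for key in keys:
        vals = np.array([f[key] for f in folds_out if f[key] is not None],
                        dtype=float)
        aggregate[key] = {"mean": float(vals.mean()) if vals.size else None,
                          "std": float(vals.std()) if vals.size else None}
    if chosen_params in (None, "published-optimum"):
        from .training import PUBLISHED_OPTIMUM
        chosen_params = dict(PUBLISHED_OPTIMUM[backend])
    return EvaluationReport(folds=folds_out, aggregate=aggregate,
                            n_selected=n_selected, params=chosen_params,
                            backend=backend)


# ---------------------------------------------------------------------------
# Model comparison


@dataclass(frozen=True)
class ModelComparison:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # model_a, model_b, mean_diff, p_adj, significant
    grouping: str


def compare_models(fold_metrics: dict[str, list[float]],
                   alpha: float = 0.05) -> ModelComparison:
    """One-way ANOVA across models on fold-level metric values + Tukey HSD."""
    if len(fold_metrics) < 2:
        raise ValidationError("need at least 2 models to compare")
    sizes = {len(v) for v in fold_metrics.values()}
    if len(sizes) != 1:
        raise ValidationError("all models must have the same fold count")
    names = list(fold_metrics)
    groups = [np.asarray(fold_metrics[m], dtype=float) for m in names]
    grand = np.concatenate(groups)
    if np.allclose(grand, grand[0]):
        pairwise = pd.DataFrame(
            [{"model_a": a, "model_b": b, "mean_diff": 0.0, "p_adj": 1.0,
              "significant": False}
             for i, a in enumerate(names) for b in names[i + 1:]])
        return ModelComparison(0.0, 1.0, pairwise,
                               ",".join(f"({m})" for m in names))
    f_stat, p_val = sps.f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = grand
    labels = np.repeat(names, [len(g) for g in groups])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    res = pd.DataFrame(tukey.summary().data[1:],
                       columns=[str(c) for c in tukey.summary().data[0]])
    pairwise = pd.DataFrame({
        "model_a": res["group1"], "model_b": res["group2"],
        "mean_diff": res["meandiff"].astype(float),
        "p_adj": res["p-adj"].astype(float),
        "significant": res["reject"].astype(bool),
    })
    return ModelComparison(float(f_stat), float(p_val), pairwise,
                           _grouping_string(names, groups, pairwise))


def _grouping_string(names: list[str], groups: list[np.ndarray],
                     pairwise: pd.DataFrame) -> str:
    """Compact ordering like "(a),(b) > (c)" from Tukey rejections."""
    means = {m: g.mean() for m, g in zip(names, groups)}
    ordered = sorted(names, key=lambda m: -means[m])

    def significant(a: str, b: str) -> bool:
        row = pairwise[((pairwise.model_a == a) & (pairwise.model_b == b))
                       | ((pairwise.model_a == b) & (pairwise.model_b == a))]
        return bool(row.significant.any())

    tiers: list[list[str]] = [[ordered[0]]]
    for m in ordered[1:]:
        if all(significant(m, other) for other in tiers[-1]):
            tiers.append([m])
        else:
            tiers[-1].append(m)
    return " > ".join(",".join(f"({m})" for m in tier) for tier in tiers)
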