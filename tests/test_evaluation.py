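"""Macro metric formulas, PR-AUC, CV, lead time, latency, model comparison."""

import numpy as np
import pytest

from fallsense.errors import StratificationError, ValidationError
from fallsense.evaluation import (ConfusionCounts, compare_models, confusion,
                                  cross_validate, lead_time, macro_metrics,
                                  measure_latency, pr_auc_per_class,
                                  replay_detection)
from fallsense.preprocessing import preprocess_recording
from fallsense.synthetic import free_fall_duration, generate_recording


class TestConfusion:
    def test_perfect_predictions(self):
        y = ["NON_FALL"] * 10 + ["SLF"] * 5 + ["FFH"] * 5
        cc = confusion(y, y)
        assert list(cc.tp) == [10, 5, 5]
        assert list(cc.fp) == [0, 0, 0]
        assert list(cc.fn) == [0, 0, 0]

    def test_all_predicted_majority(self):
        y = ["NON_FALL"] * 10 + ["SLF"] * 5 + ["FFH"] * 5
        pred = ["NON_FALL"] * 20
        cc = confusion(y, pred)
        by = dict(zip(cc.classes, cc.fn))
        assert by["SLF"] == 5
        assert dict(zip(cc.classes, cc.fp))["NON_FALL"] == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            confusion([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["SLF"], ["SLF", "FFH"])


class TestMacroMetrics:
    def test_perfect_classifier_scores_one(self):
        y = ["NON_FALL"] * 10 + ["SLF"] * 5 + ["FFH"] * 5
        mm = macro_metrics(confusion(y, y))
        assert mm.accuracy == mm.sensitivity == mm.specificity == 1.0
        assert mm.f1 == mm.mcc == 1.0

    def test_single_class_predictor_zero_denominator_guard(self):
        """A constant predictor produces zero-denominator MCC/specificity
        terms for its own class; those terms contribute 0."""
        y = ["NON_FALL"] * 10 + ["SLF"] * 5 + ["FFH"] * 5
        mm = macro_metrics(confusion(y, ["NON_FALL"] * 20))
        assert np.isfinite([mm.accuracy, mm.sensitivity, mm.specificity,
                            mm.f1, mm.mcc]).all()
        # NON_FALL one-vs-rest: TN=0, FN=0 -> MCC denominator 0 -> term 0;
        # SLF/FFH: TP=0 -> MCC numerator 0*TN-0*FN=0 -> terms 0
        assert mm.mcc == 0.0
        assert mm.sensitivity == pytest.approx(1 / 3)

    def test_hand_evaluated_confusion_table(self):
        """Spreadsheet-style direct evaluation of the five formulas."""
        cc = ConfusionCounts(
            classes=("NON_FALL", "SLF", "FFH"),
            tp=np.array([8, 3, 2]), fn=np.array([2, 2, 3]),
            fp=np.array([4, 1, 2]), tn=np.array([6, 14, 13]))
        mm = macro_metrics(cc)

        def binary(tp, fn, fp, tn):
            acc = (tp + tn) / (tp + tn + fp + fn)
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            f1 = 2 * tp / (2 * tp + fp + fn)
            mcc = (tp * tn - fp * fn) / (
                ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5)
            return acc, sens, spec, f1, mcc

        rows = [binary(8, 2, 4, 6), binary(3, 2, 1, 14), binary(2, 3, 2, 13)]
        expected = [sum(col) / 3 for col in zip(*rows)]
        got = [mm.accuracy, mm.sensitivity, mm.specificity, mm.f1, mm.mcc]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_metric_bounds(self):
        rng = np.random.default_rng(0)
        labels = np.array(["NON_FALL", "SLF", "FFH"], dtype=object)
        for _ in range(20):
            y = labels[rng.integers(0, 3, 30)]
            p = labels[rng.integers(0, 3, 30)]
            mm = macro_metrics(confusion(y, p))
            for v in (mm.accuracy, mm.sensitivity, mm.specificity, mm.f1):
                assert 0.0 <= v <= 1.0
            assert -1.0 <= mm.mcc <= 1.0


class TestPrAuc:
    def test_perfectly_ranked_scores(self):
        y = ["SLF"] * 5 + ["NON_FALL"] * 15
        scores = np.zeros((20, 2))
        scores[:5, 1] = 0.9
        scores[:5, 0] = 0.1
        scores[5:, 0] = 0.9
        scores[5:, 1] = 0.1
        out = pr_auc_per_class(y, scores, ("NON_FALL", "SLF"))
        assert out["NON_FALL"] == pytest.approx(1.0)
        assert out["SLF"] == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        """Uninformative scores give PR-AUC ~ class prevalence at large n."""
        rng = np.random.default_rng(1)
        n, pi = 10000, 0.2
        y = np.where(rng.uniform(size=n) < pi, "SLF", "NON_FALL").astype(object)
        raw = rng.uniform(size=(n, 2))
        scores = raw / raw.sum(axis=1, keepdims=True)
        out = pr_auc_per_class(y, scores, ("NON_FALL", "SLF"))
        assert out["SLF"] == pytest.approx(pi, abs=0.02)

    def test_single_positive_ranked_first(self):
        y = ["SLF"] + ["NON_FALL"] * 9
        scores = np.column_stack([np.linspace(0.1, 0.9, 10),
                                  np.linspace(0.9, 0.1, 10)])
        out = pr_auc_per_class(y, scores, ("NON_FALL", "SLF"))
        assert out["SLF"] == pytest.approx(1.0)

    def test_absent_class_reported_missing(self):
        y = ["NON_FALL"] * 10
        scores = np.tile([0.5, 0.3, 0.2], (10, 1))
        out = pr_auc_per_class(y, scores, ("NON_FALL", "SLF", "FFH"))
        assert out["SLF"] is None and out["FFH"] is None


class TestLeadTime:
    def test_half_second_before_impact(self):
        assert lead_time(2.0, 2.5) == pytest.approx(500.0)

    def test_detection_after_impact_rejected(self):
        with pytest.raises(ValidationError):
            lead_time(2.5, 2.0)

    def test_expected_ffh_lead_equals_free_fall_duration(self):
        assert free_fall_duration(2.0) * 1000 == pytest.approx(638.6, abs=0.5)
        assert free_fall_duration(0.5) * 1000 == pytest.approx(319.3, abs=0.5)
        assert free_fall_duration(0.5) * 1000 > 130.0  # airbag margin


@pytest.fixture(scope="module")
def small_cv_windows(small_dataset):
    windows = []
    for rec in small_dataset:
        windows.extend(preprocess_recording(rec))
    return windows


FAST = {"n_estimators": 150, "max_depth": 5, "learning_rate": 0.2}


class TestCrossValidate:
    def test_separable_synthetic_reaches_high_macro_f1(self, small_cv_windows):
        rep = cross_validate(small_cv_windows, k=5, backend="xgb",
                             params=FAST, augment_level=2, seed=0)
        assert rep.aggregate["macro_f1"]["mean"] >= 0.90
        assert len(rep.folds) == 5

    def test_shuffled_labels_give_chance_level(self, small_cv_windows):
        import copy
        from fallsense.preprocessing import LabeledWindow
        rng = np.random.default_rng(0)
        labels = [w.label for w in small_cv_windows]
        shuffled = [LabeledWindow(w.window, l, w.origin) for w, l in
                    zip(small_cv_windows, rng.permutation(labels))]
        rep = cross_validate(shuffled, k=5, backend="xgb", params=FAST,
                             augment_level=None, seed=0)
        assert rep.aggregate["macro_f1"]["mean"] == pytest.approx(1 / 3, abs=0.1)

    def test_stratification_preserves_fold_proportions(self, small_cv_windows):
        from sklearn.model_selection import StratifiedKFold
        labels = np.array([w.label for w in small_cv_windows], dtype=object)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, te in skf.split(labels, labels):
            for c in set(labels):
                global_frac = (labels == c).mean()
                fold_frac = (labels[te] == c).mean()
                assert abs(fold_frac - global_frac) * len(te) <= 1 + 1e-9

    def test_class_smaller_than_k_rejected(self, small_cv_windows):
        few = [w for w in small_cv_windows if w.label != "FFH"]
        few += [w for w in small_cv_windows if w.label == "FFH"][:3]
        with pytest.raises(StratificationError):
            cross_validate(few, k=5, backend="xgb", params=FAST, seed=0)


class TestReplay:
    @pytest.fixture(scope="class")
    def detector(self, small_cv_windows):
        from fallsense.features import build_matrix
        from fallsense.training import fit
        return fit("xgb", build_matrix(small_cv_windows), params=FAST, seed=0)

    def test_ffh_lead_exceeds_airbag_margin(self, detector):
        rec = generate_recording("FFH", "forward 0.5 m", seed=101)
        out = replay_detection(detector, rec)
        assert out.detected
        assert out.lead_time_ms >= 130.0

    def test_lead_time_bounded_by_critical_duration(self, detector):
        rec = generate_recording("FFH", "forward 2.0 m", seed=102)
        out = replay_detection(detector, rec)
        assert out.detected
        # detection cannot precede the loss of balance by construction of
        # the labeling rule, so the lead is at most the critical duration
        assert out.lead_time_ms <= rec.annotation.critical_duration * 1000 + 1e-6


class TestLatency:
    def test_positive_with_host_metadata(self, planted, planted_model):
        rep = measure_latency(planted_model, planted.X)
        assert rep["ms_per_window"] > 0
        assert rep["n_windows"] == planted.N
        assert "machine" in rep["host"]

    def test_too_few_windows_rejected(self, planted, planted_model):
        with pytest.raises(ValidationError):
            measure_latency(planted_model, planted.X.iloc[:50])


class TestCompareModels:
    def test_identical_values_no_significance(self):
        table = {"a": [0.9] * 5, "b": [0.9] * 5, "c": [0.9] * 5}
        cmp = compare_models(table)
        assert cmp.f_statistic == 0.0
        assert not cmp.pairwise.significant.any()

    def test_separated_models_detected_and_ordered(self):
        rng = np.random.default_rng(0)
        table = {"good": list(0.9 + rng.normal(0, 1e-3, 5)),
                 "bad": list(0.5 + rng.normal(0, 1e-3, 5))}
        cmp = compare_models(table)
        assert cmp.p_value < 0.001
        assert cmp.pairwise.significant.all()
        assert cmp.grouping.startswith("(good)")
        # hand check of the one-way ANOVA F statistic
        a, b = np.array(table["good"]), np.array(table["bad"])
        grand = np.concatenate([a, b]).mean()
        ssb = 5 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_hand = (ssb / 1) / (ssw / 8)
        assert cmp.f_statistic == pytest.approx(f_hand, rel=1e-9)

    def test_three_models_three_pairs(self):
        rng = np.random.default_rng(1)
        table = {m: list(v + rng.normal(0, 0.01, 5))
                 for m, v in (("a", 0.9), ("b", 0.8), ("c", 0.7))}
        cmp = compare_models(table)
        assert len(cmp.pairwise) == 3

    def test_single_model_rejected(self):
        with pytest.raises(ValidationError):
            compare_models({"only": [0.9] * 5})
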