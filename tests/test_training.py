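"""Inverse-frequency weighting, search spaces, backends, Bayesian search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallsense.errors import BackendUnavailableError, ValidationError
from fallsense.training import (PUBLISHED_OPTIMUM, SEARCH_SPACES, TrainedModel,
                                bayes_optimize, compute_sample_weights, fit,
                                midpoint_params, validate_params)


class TestSampleWeights:
    def test_balanced_labels_give_unit_weights(self):
        w = compute_sample_weights(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        assert np.allclose(w, 1.0)

    def test_imbalanced_two_class_hand_values(self):
        # N=100, K=2, counts (80, 20) -> 100/(2*80)=0.625 and 100/(2*20)=2.5
        w = compute_sample_weights(["maj"] * 80 + ["min"] * 20)
        assert np.allclose(w[:80], 0.625)
        assert np.allclose(w[80:], 2.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["NON_FALL", "SLF", "FFH"]),
                    min_size=1, max_size=200))
    def test_weights_sum_to_n(self, labels):
        w = compute_sample_weights(labels)
        assert np.isclose(w.sum(), len(labels), rtol=1e-9)

    def test_minority_gets_strictly_larger_weight(self):
        w = compute_sample_weights(["a"] * 50 + ["b"] * 10 + ["c"] * 2)
        assert w[0] < w[50] < w[-1]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compute_sample_weights([])


class TestSearchSpace:
    def test_published_ranges_frozen(self):
        xgb = SEARCH_SPACES["xgb"]
        assert xgb["learning_rate"] == ("log-uniform", 0.005, 0.30)
        assert xgb["n_estimators"] == ("integer-uniform", 100, 800)
        assert xgb["max_depth"] == ("integer-uniform", 3, 10)
        assert xgb["subsample"] == ("uniform", 0.50, 1.00)
        assert xgb["colsample_bytree"] == ("uniform", 0.30, 1.00)
        assert xgb["gamma"] == ("uniform", 0.0, 5.0)
        assert xgb["min_child_weight"] == ("integer-uniform", 1, 10)
        lgbm = SEARCH_SPACES["lgbm"]
        assert lgbm["num_leaves"] == ("integer-uniform", 15, 255)
        assert lgbm["min_child_weight"] == ("log-uniform", 1e-3, 10.0)
        cat = SEARCH_SPACES["cat"]
        assert cat["bagging_temperature"] == ("uniform", 0.0, 1.0)
        assert cat["l2_leaf_reg"] == ("log-uniform", 1e-3, 10.0)

    def test_published_optima_lie_inside_their_ranges(self):
        for backend, params in PUBLISHED_OPTIMUM.items():
            validate_params(backend, params)  # must not raise

    def test_out_of_range_params_rejected(self):
        with pytest.raises(ValidationError):
            validate_params("xgb", {"learning_rate": 0.5})
        with pytest.raises(ValidationError):
            validate_params("xgb", {"max_depth": 12})
        with pytest.raises(ValidationError):
            validate_params("xgb", {"not_a_param": 1})


SMALL = {"n_estimators": 120, "max_depth": 4, "learning_rate": 0.2}


class TestFitPredict:
    def test_separable_training_fit(self, planted):
        model = fit("xgb", planted, params=SMALL, seed=0)
        labels, _ = model.predict(planted)
        assert (labels == planted.y).mean() >= 0.99

    def test_scores_sum_to_one(self, planted):
        model = fit("xgb", planted, params=SMALL, seed=0)
        _, proba = model.predict(planted)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_unit_weights_match_inverse_frequency_on_balanced_data(self, planted):
        idx = np.concatenate([np.nonzero(planted.y == c)[0][:80]
                              for c in ("NON_FALL", "SLF", "FFH")])
        balanced = planted.rows(idx)
        a = fit("xgb", balanced, weights=np.ones(balanced.N), params=SMALL, seed=0)
        b = fit("xgb", balanced, weights=None, params=SMALL, seed=0)
        np.testing.assert_allclose(a.predict_proba(balanced),
                                   b.predict_proba(balanced), atol=1e-9)

    def test_out_of_bounds_params_rejected_at_fit(self, planted):
        with pytest.raises(ValidationError):
            fit("xgb", planted, params={"max_depth": 50}, seed=0)

    def test_lgbm_backend_same_contract(self, planted):
        model = fit("lgbm", planted,
                    params={"n_estimators": 120, "max_depth": 4,
                            "learning_rate": 0.2, "num_leaves": 31}, seed=0)
        labels, proba = model.predict(planted)
        assert (labels == planted.y).mean() >= 0.99
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_cat_backend_unavailable_error_names_backend(self, planted):
        with pytest.raises(BackendUnavailableError, match="cat"):
            fit("cat", planted, seed=0)

    def test_registry_mismatch_lists_missing_columns(self, planted):
        model = fit("xgb", planted, params=SMALL, seed=0)
        with pytest.raises(Exception, match="planted_signal"):
            model.predict(planted.X.drop(columns=["planted_signal"]))

    def test_save_load_round_trip(self, planted, tmp_path):
        model = fit("xgb", planted, params=SMALL, seed=0)
        model.save(tmp_path / "m.bin")
        back = TrainedModel.load(tmp_path / "m.bin")
        np.testing.assert_allclose(model.predict_proba(planted),
                                   back.predict_proba(planted), atol=1e-7)
        assert back.registry == model.registry


class TestBayesOptimize:
    def test_single_trial_returns_that_configuration(self, planted):
        params, log = bayes_optimize(planted, backend="xgb", n_trials=1, seed=0)
        assert len(log) == 1
        assert params == log[0]["params"]
        validate_params("xgb", params)

    def test_deterministic_under_seed(self, planted):
        a, _ = bayes_optimize(planted, backend="xgb", n_trials=3, seed=4)
        b, _ = bayes_optimize(planted, backend="xgb", n_trials=3, seed=4)
        assert a == b

    def test_beats_midpoint_baseline_on_planted_data(self, planted):
        """25-trial search must reach at least the macro-F1 of the search
        space's midpoint configuration on the same inner split."""
        from sklearn.metrics import f1_score
        from sklearn.model_selection import train_test_split
        params, log = bayes_optimize(planted, backend="xgb", n_trials=25, seed=0)
        best = max(t["macro_f1"] for t in log)
        idx = np.arange(planted.N)
        tr, va = train_test_split(idx, test_size=0.2, stratify=planted.y,
                                  random_state=0)
        mid = fit("xgb", planted.rows(tr), params=midpoint_params("xgb"), seed=0)
        mid_f1 = f1_score(planted.y[va], mid.predict(planted.rows(va))[0],
                          average="macro")
        assert best >= mid_f1 - 1e-9
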