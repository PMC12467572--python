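"""Windowing, denoising, labeling, augmentation and stratified splitting."""

import numpy as np
import pytest

from fallsense.errors import ParameterError, StratificationError
from fallsense.preprocessing import (LabeledWindow, augment, compute_smv,
                                     label_windows, median_filter,
                                     segment_windows, stratified_split)

from conftest import make_recording, make_window


class TestMedianFilter:
    def test_constant_series_unchanged(self):
        x = np.full(40, 3.5)
        assert np.array_equal(median_filter(x, 5), x)

    def test_single_spike_removed(self):
        assert np.array_equal(median_filter(np.array([1.0, 1, 9, 1, 1]), 3),
                              np.ones(5))

    def test_kernel_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=(40, 6))
        assert np.array_equal(median_filter(x, 1), x)

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            median_filter(np.zeros(40), 4)

    def test_channels_filtered_independently(self):
        x = np.zeros((40, 6))
        x[10, 0] = 5.0  # spike only on channel 0
        out = median_filter(x, 5)
        assert out[10, 0] == 0.0
        assert np.array_equal(out[:, 1:], x[:, 1:])


class TestSmv:
    @pytest.mark.parametrize("vec,expected", [
        ((0, 0, 1), 1.0), ((3, 4, 0), 5.0), ((0, 0, 0), 0.0)])
    def test_known_values(self, vec, expected):
        assert compute_smv(np.array([vec], dtype=float))[0] == expected


class TestSegmentation:
    @pytest.mark.parametrize("n,stride,expected", [
        (120, 40, 3), (100, 40, 2), (80, 20, 3)])
    def test_window_counts(self, n, stride, expected):
        rec = make_recording(n=n)
        assert len(segment_windows(rec, stride=stride)) == expected

    def test_too_short_recording_gives_empty(self):
        assert segment_windows(make_recording(n=30)) == []

    def test_windows_carry_end_times_on_grid(self):
        rec = make_recording(n=120)
        ws = segment_windows(rec, stride=40)
        assert [w.end_time for w in ws] == pytest.approx(
            [39 / 40, 79 / 40, 119 / 40])


class TestLabeling:
    def _ffh_recording(self):
        # loss of balance at 2.0 s, impact at 2.5 s
        return make_recording(n=160, klass="FFH", subtype="forward 2.0 m",
                              lob=2.0, impact=2.5)

    def test_window_ending_in_critical_phase_gets_fall_label(self):
        rec = self._ffh_recording()
        ws = segment_windows(rec, stride=1)
        labeled = label_windows(ws, rec.annotation)
        by_end = {lw.window.end_time: lw.label for lw in labeled}
        assert by_end[2.1 - 1 / 40] == "FFH"   # 0.1 s after balance loss

    def test_window_ending_before_balance_loss_is_non_fall(self):
        rec = self._ffh_recording()
        labeled = label_windows(segment_windows(rec, stride=1), rec.annotation)
        assert all(lw.label == "NON_FALL"
                   for lw in labeled if lw.window.end_time < 2.0)

    def test_window_ending_at_impact_discarded(self):
        rec = self._ffh_recording()
        labeled = label_windows(segment_windows(rec, stride=1), rec.annotation)
        ends = [lw.window.end_time for lw in labeled]
        assert max(ends) < 2.5
        assert 2.5 not in ends

    def test_non_fall_recording_all_non_fall(self):
        rec = make_recording(n=120)
        labeled = label_windows(segment_windows(rec, stride=40), rec.annotation)
        assert {lw.label for lw in labeled} == {"NON_FALL"}


class TestAugmentation:
    def _windows(self, n=8):
        rng = np.random.default_rng(1)
        return [LabeledWindow(make_window(rng.normal(0, 1, (40, 6))), "SLF")
                for _ in range(n)]

    def test_three_copies_per_window_plus_originals(self):
        ws = self._windows(8)
        out = augment(ws, level=2, seed=0)
        assert len(out) == 4 * 8
        assert sum(1 for w in out if w.origin == "augmented") == 24
        assert all(w.label == "SLF" for w in out)

    def test_deterministic_under_seed(self):
        ws = self._windows(4)
        a = augment(ws, level=1, seed=5)
        b = augment(ws, level=1, seed=5)
        assert all(np.array_equal(x.window.samples, y.window.samples)
                   for x, y in zip(a, b))

    def test_level_one_jitter_sigma(self):
        """Monte-Carlo check: jitter noise on a constant accel channel has
        sample std within 3x of the nominal 0.01 g."""
        const = np.zeros((40, 6))
        const[:, 2] = 1.0
        ws = [LabeledWindow(make_window(const.copy()), "NON_FALL")
              for _ in range(50)]
        out = augment(ws, level=1, seed=3)
        jittered = out[len(ws)::3]  # first transform of each window
        stds = [np.std(w.window.samples[:, 2]) for w in jittered]
        assert 0.01 / 3 < np.mean(stds) < 0.01 * 3

    def test_invalid_level_rejected(self):
        with pytest.raises(ParameterError):
            augment(self._windows(1), level=5, seed=0)


class TestStratifiedSplit:
    def _windows(self, counts):
        out = []
        for label, n in counts.items():
            out += [LabeledWindow(make_window(), label) for _ in range(n)]
        return out

    def test_per_class_rounding(self):
        ws = self._windows({"NON_FALL": 100, "SLF": 40, "FFH": 20})
        train, test = stratified_split(ws, test_fraction=0.2, seed=0)
        counts = {c: sum(1 for w in test if w.label == c)
                  for c in ("NON_FALL", "SLF", "FFH")}
        assert counts == {"NON_FALL": 20, "SLF": 8, "FFH": 4}

    def test_partition_property(self):
        ws = self._windows({"NON_FALL": 37, "SLF": 13, "FFH": 9})
        train, test = stratified_split(ws, test_fraction=0.3, seed=1)
        assert len(train) + len(test) == len(ws)
        ids = lambda lst: {id(w) for w in lst}
        assert ids(train) | ids(test) == ids(ws)
        assert not ids(train) & ids(test)

    def test_balanced_half_split(self):
        ws = self._windows({"NON_FALL": 10, "SLF": 10, "FFH": 10})
        train, test = stratified_split(ws, test_fraction=0.5, seed=2)
        for c in ("NON_FALL", "SLF", "FFH"):
            assert sum(1 for w in test if w.label == c) == 5

    def test_augmented_never_in_test(self):
        ws = self._windows({"NON_FALL": 20, "SLF": 10})
        ws += augment(ws[:4], level=1, seed=0)[4:]
        train, test = stratified_split(ws, test_fraction=0.25, seed=0)
        assert all(w.origin == "real" for w in test)

    def test_tiny_class_rejected(self):
        ws = self._windows({"NON_FALL": 10, "SLF": 1})
        with pytest.raises(StratificationError):
            stratified_split(ws, test_fraction=0.2, seed=0)
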