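"""Tests of resampling, windowing, gravity correction and spectral features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chestmotion.preprocess import (
    FeatureSequence,
    WindowSlice,
    features_to_table,
    gravity_correct,
    resample,
    slice_windows,
    spectral_features,
    table_to_features,
)
from chestmotion.signal_synth import AccelStream


def make_stream(values: np.ndarray, rate: float = 10.0) -> AccelStream:
    n = len(values)
    return AccelStream(rate=rate, t=np.arange(n) / rate,
                       ax=values[:, 0], ay=values[:, 1], az=values[:, 2])


class TestResample:
    def test_downsample_halves_length(self):
        s = make_stream(np.zeros((200, 3)), rate=20.0)
        out = resample(s, 10.0)
        assert out.rate == 10.0
        assert len(out) == 100

    def test_constant_stream_unchanged(self):
        s = make_stream(np.full((200, 3), 7.5), rate=20.0)
        out = resample(s, 10.0)
        assert np.allclose(out.values, 7.5)

    def test_same_rate_passthrough(self):
        s = make_stream(np.random.default_rng(0).normal(size=(50, 3)), rate=10.0)
        assert resample(s, 10.0) is s

    def test_sinusoid_against_analytic_values(self):
        # 1 Hz sine at 20 Hz, downsampled to 10 Hz, vs the analytic curve
        t = np.arange(400) / 20.0
        vals = np.column_stack([np.sin(2 * np.pi * 1.0 * t)] * 3)
        out = resample(make_stream(vals, rate=20.0), 10.0)
        expected = np.sin(2 * np.pi * 1.0 * out.t)
        assert np.max(np.abs(out.ax - expected)) <= 0.005  # 0.5% of amplitude

    def test_upsampling_rejected(self):
        s = make_stream(np.zeros((50, 3)), rate=10.0)
        with pytest.raises(ValueError, match="upsample"):
            resample(s, 20.0)


class TestSliceWindows:
    def test_600_samples_gives_59_windows(self):
        s = make_stream(np.zeros((600, 3)))
        assert len(slice_windows(s)) == 59

    def test_exact_width_gives_one_window(self):
        s = make_stream(np.zeros((20, 3)))
        ws = slice_windows(s)
        assert len(ws) == 1
        assert ws[0].start_index == 0

    def test_short_stream_gives_empty_list(self):
        s = make_stream(np.zeros((19, 3)))
        assert slice_windows(s) == []

    def test_majority_label_and_tie_rule(self):
        s = make_stream(np.zeros((20, 3)))
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        assert slice_windows(s, labels=labels)[0].label == "a"  # tie -> first sample
        labels2 = np.array(["a"] * 9 + ["b"] * 11, dtype=object)
        assert slice_windows(s, labels=labels2)[0].label == "b"

    @given(
        n=st.integers(min_value=20, max_value=2000),
        width=st.integers(min_value=2, max_value=50),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    @settings(max_examples=60, deadline=None)
    def test_window_count_formula(self, n, width, overlap):
        hop = int(round(width * (1 - overlap)))
        if n < width or hop < 1:
            return
        s = make_stream(np.zeros((n, 3)))
        ws = slice_windows(s, width=width, overlap=overlap)
        assert len(ws) == (n - width) // hop + 1
        starts = [w.start_index for w in ws]
        assert starts == sorted(starts)


class TestGravityCorrect:
    def test_constant_window_maps_to_zero(self):
        w = WindowSlice(np.tile([0.0, 0.0, 9.81], (20, 1)), 0, 10.0)
        assert np.all(gravity_correct(w).values == 0.0)

    def test_zero_mean_postcondition(self):
        rng = np.random.default_rng(1)
        w = WindowSlice(rng.normal(5, 2, (20, 3)), 0, 10.0)
        out = gravity_correct(w)
        assert np.max(np.abs(out.values.mean(axis=0))) <= 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        w = WindowSlice(rng.normal(size=(20, 3)), 0, 10.0)
        once = gravity_correct(w)
        twice = gravity_correct(once)
        assert np.allclose(once.values, twice.values)


class TestSpectralFeatures:
    def test_zero_window(self):
        w = WindowSlice(np.zeros((20, 3)), 0, 10.0)
        assert np.all(spectral_features(w).spectra == 0.0)

    def test_pure_tone_lands_in_bin_5(self):
        """cos at 2.5 Hz, 10 Hz/20 samples -> bin 5; oracle is the direct DFT sum."""
        t = np.arange(20) / 10.0
        vals = np.zeros((20, 3))
        vals[:, 1] = np.cos(2 * np.pi * 2.5 * t)
        w = WindowSlice(vals, 0, 10.0)
        spec = spectral_features(w).spectra
        # direct DFT-sum oracle at bin 5 on the mean-removed signal
        x = vals[:, 1] - vals[:, 1].mean()
        oracle = abs(np.sum(x * np.exp(-2j * np.pi * 5 * np.arange(20) / 20)))
        assert spec[5, 1] == pytest.approx(oracle, rel=1e-12)
        mask = np.ones(11, dtype=bool)
        mask[5] = False
        assert np.all(spec[mask, 1] <= 1e-9)
        assert np.all(spec[:, [0, 2]] <= 1e-9)

    def test_parseval_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.normal(size=(20, 3))
            w = WindowSlice(vals, 0, 10.0)
            spec = spectral_features(w).spectra
            corrected = vals - vals.mean(axis=0)
            for a in range(3):
                # rebuild the two-sided power from the one-sided magnitudes
                two_sided = np.concatenate([spec[:, a] ** 2, spec[1:-1, a] ** 2])
                lhs = np.sum(corrected[:, a] ** 2)
                assert lhs == pytest.approx(np.sum(two_sided) / 20, rel=1e-9, abs=1e-12)

    def test_dc_bin_zero_after_correction(self):
        rng = np.random.default_rng(4)
        w = WindowSlice(rng.normal(9, 3, (20, 3)), 0, 10.0)
        spec = spectral_features(w).spectra
        assert np.all(spec[0] <= 1e-9 * max(1.0, np.abs(w.values).max()))

    def test_wrong_width_rejected(self):
        w = WindowSlice(np.zeros((10, 3)), 0, 10.0)
        with pytest.raises(ValueError, match="width"):
            spectral_features(w)

    def test_bin_width(self):
        w = WindowSlice(np.zeros((20, 3)), 0, 10.0)
        assert spectral_features(w).bin_hz == pytest.approx(0.5)


class TestFeatureTable:
    def test_round_trip(self):
        rng = np.random.default_rng(5)
        feats = [
            FeatureSequence(np.abs(rng.normal(size=(11, 3))), 0.5, label="walk",
                            subject_id="A", start_index=i * 10)
            for i in range(4)
        ]
        back = table_to_features(features_to_table(feats))
        assert len(back) == 4
        for f, b in zip(feats, back):
            assert np.allclose(f.spectra, b.spectra)
            assert (b.label, b.subject_id, b.start_index) == ("walk", "A", f.start_index)
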