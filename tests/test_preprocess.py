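"""Denoising, reference location, windowing, feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgorigin import _wavelet
from ecgorigin.ecg_data import Dataset, ECGRecording, LEAD_NAMES
from ecgorigin.preprocess import (WindowConfig, build_feature_matrix,
                                  denoise_lead, denoise_recording,
                                  extract_window, locate_reference)


def _beat(T=1000, peak=500, amp=1.5):
    t = np.arange(T)
    return (amp * np.exp(-((t - peak) ** 2) / (2 * 8.0 ** 2))
            - 0.4 * np.exp(-((t - peak - 30) ** 2) / (2 * 12.0 ** 2)))


def _recording(signal, r_peak=None, label="LC"):
    return ECGRecording(patient_id="p", recording_id="r", signal=signal,
                        r_peak_index=r_peak, label=label)


class TestWaveletTransform:
    @pytest.mark.parametrize("n", [64, 999, 1000, 2400])
    def test_perfect_reconstruction(self, n, rng):
        x = rng.normal(size=n)
        a, d, pads = _wavelet.wavedec(x)
        np.testing.assert_allclose(_wavelet.waverec(a, d, pads), x, atol=1e-6)

    def test_sure_threshold_minimizes_risk(self, rng):
        # brute-force oracle: evaluate the SURE risk on a dense grid and
        # confirm the selected threshold attains the minimum
        d = rng.normal(0, 1, 200) + np.where(rng.random(200) < 0.1, 5.0, 0.0)
        t_star = _wavelet.sure_threshold(d)

        def risk(t):
            return (len(d) - 2 * np.sum(np.abs(d) <= t)
                    + np.sum(np.minimum(d ** 2, t ** 2)))

        grid = np.linspace(0, np.abs(d).max(), 2000)
        assert risk(t_star) <= min(risk(t) for t in grid) + 1e-9


class TestDenoise:
    def test_zero_fixed_point(self):
        assert np.all(denoise_lead(np.zeros(1000)) == 0)

    def test_constant_preserved(self):
        c = np.full(800, 2.5)
        np.testing.assert_allclose(denoise_lead(c), c, atol=1e-7)

    def test_mse_reduction_monte_carlo(self):
        """Denoising strictly reduces MSE to the clean beat (seeded trials)."""
        clean = _beat()
        wins = 0
        trials = 40
        for s in range(trials):
            noisy = clean + np.random.default_rng(s).normal(0, 0.05, clean.size)
            den = denoise_lead(noisy)
            assert den.shape == noisy.shape
            if np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2):
                wins += 1
        assert wins == trials

    def test_idempotent_within_tolerance(self):
        noisy = _beat() + np.random.default_rng(3).normal(0, 0.05, 1000)
        d1 = denoise_lead(noisy)
        d2 = denoise_lead(d1)
        assert np.linalg.norm(d2 - d1) / np.linalg.norm(d1) < 0.01

    def test_short_series_identity_with_warning(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="shorter"):
            out = denoise_lead(x)
        np.testing.assert_array_equal(out, x)

    def test_recording_leadwise_independence(self, rng):
        sig = rng.normal(size=(12, 600)) + _beat(600, 300)
        rec = _recording(sig)
        den = denoise_recording(rec)
        # permuting leads before equals permuting after
        perm = rng.permutation(12)
        den_rows = np.vstack([denoise_lead(sig[i]) for i in perm])
        np.testing.assert_allclose(den.signal[perm], den_rows)
        assert den.label == rec.label and den.r_peak_index == rec.r_peak_index


class TestReferenceLocation:
    def test_annotated_passthrough(self, rng):
        rec = _recording(rng.normal(size=(12, 400)), r_peak=200)
        assert locate_reference(rec) == 200

    def test_fallback_argmax_lead_ii(self, rng):
        sig = rng.normal(0, 0.01, size=(12, 400))
        sig[LEAD_NAMES.index("II")] = _beat(400, peak=150)
        assert locate_reference(_recording(sig)) == 150

    def test_constant_lead_ii_ties_to_first(self):
        sig = np.zeros((12, 50))
        assert locate_reference(_recording(sig)) == 0


class TestWindowConfig:
    @given(W=st.integers(1, 2000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_split_invariants(self, W):
        cfg = WindowConfig(W)
        assert cfg.pre + cfg.post == W
        assert cfg.pre == W // 2
        offs = cfg.offsets
        assert len(offs) == W
        assert 0 not in offs

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            WindowConfig(0)


class TestExtractWindow:
    def test_interior_window(self, rng):
        sig = rng.normal(size=(12, 1000))
        out = extract_window(_recording(sig, r_peak=500), WindowConfig(200))
        np.testing.assert_array_equal(out, sig[:, 400:600])

    def test_edge_padding_brute_force(self, rng):
        # oracle: compute expected columns by clamping indices by hand
        sig = rng.normal(size=(12, 300))
        cfg = WindowConfig(200)
        out = extract_window(_recording(sig, r_peak=10), cfg)
        expected = np.empty((12, 200))
        for j, src in enumerate(range(10 - cfg.pre, 10 + cfg.post)):
            expected[:, j] = sig[:, min(max(src, 0), 299)]
        np.testing.assert_array_equal(out, expected)
        # first 90 columns are copies of column 0
        assert np.all(out[:, :90] == sig[:, [0]])

    def test_single_sample_window(self, rng):
        sig = rng.normal(size=(12, 100))
        out = extract_window(_recording(sig, r_peak=42), WindowConfig(1))
        np.testing.assert_array_equal(out, sig[:, [42]])

    @given(T=st.integers(1, 300), r=st.data(), W=st.integers(1, 400))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_width_always_W(self, T, r, W):
        r_peak = r.draw(st.integers(0, T - 1))
        sig = np.arange(12 * T, dtype=float).reshape(12, T)
        out = extract_window(_recording(sig, r_peak=r_peak), WindowConfig(W))
        assert out.shape == (12, W)


class TestFeatureMatrix:
    def test_shape_and_alignment(self, rng):
        recs = [ECGRecording(patient_id=f"p{i}", recording_id=f"r{i}",
                             signal=rng.normal(size=(12, 800)),
                             r_peak_index=400, label="LC")
                for i in range(5)]
        fm = build_feature_matrix(Dataset(recs), WindowConfig(320),
                                  denoise=False)
        assert fm.values.shape == (5, 3840)
        assert fm.recording_ids == [f"r{i}" for i in range(5)]

    def test_feature_name_addresses_window_column(self, rng):
        """(V1, +10) is the 10th point counting the reference sample as 1."""
        sig = rng.normal(size=(12, 500))
        rec = ECGRecording(patient_id="p", recording_id="r", signal=sig,
                           r_peak_index=250, label="LC")
        cfg = WindowConfig(100)
        fm = build_feature_matrix(Dataset([rec]), cfg, denoise=False)
        col = fm.column_of("V1", 10)
        v1 = LEAD_NAMES.index("V1")
        # offset +10 = window column pre + 9 = sample r + 9
        assert fm.values[0, col] == sig[v1, 250 + 9]
        neg = fm.column_of("II", -3)
        assert fm.values[0, neg] == sig[LEAD_NAMES.index("II"), 250 - 3]

    def test_empty_dataset(self):
        fm = build_feature_matrix(Dataset([]), WindowConfig(20), denoise=False)
        assert fm.values.shape == (0, 240)
        assert len(fm.feature_names) == 240

    def test_unlabeled_recording_rejected(self, rng):
        rec = ECGRecording(patient_id="p", recording_id="nolabel",
                           signal=rng.normal(size=(12, 100)))
        with pytest.raises(ValueError, match="nolabel"):
            build_feature_matrix(Dataset([rec]), WindowConfig(10))

    def test_hdf5_round_trip(self, tmp_path, rng):
        recs = [ECGRecording(patient_id="p", recording_id="r",
                             signal=rng.normal(size=(12, 200)),
                             r_peak_index=100, label="TV")]
        fm = build_feature_matrix(Dataset(recs), WindowConfig(64),
                                  denoise=False)
        from ecgorigin.preprocess import FeatureMatrix
        fm.to_hdf5(tmp_path / "fm.h5")
        back = FeatureMatrix.from_hdf5(tmp_path / "fm.h5")
        np.testing.assert_array_equal(back.values, fm.values)
        assert back.feature_names == fm.feature_names
        assert back.labels == fm.labels
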