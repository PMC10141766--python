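"""Filter responses, XCorr, SOBI recovery and artifact zeroing."""

import numpy as np
import pytest

import micompen as mc
from conftest import amari_index, ar1
from micompen.eeg_io import RawRecording
from micompen.preprocess import (DegenerateSignalError, flag_and_zero,
                                 score_components, sobi, xcorr)


def _sine_rec(freq, fs=250.0, n=5000):
    t = np.arange(n) / fs
    return RawRecording(np.sin(2 * np.pi * freq * t)[None, :], fs,
                        ["C1"], ["EEG"])


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestFilters:
    def test_notch_kills_line_keeps_signal(self):
        sl = np.s_[:, 1000:-1000]   # steady state, away from edge transients
        out50 = mc.notch_filter(_sine_rec(50.0), 50.0)
        assert _rms(out50.data[sl]) < 0.01 * _rms(_sine_rec(50.0).data[sl])
        out10 = mc.notch_filter(_sine_rec(10.0), 50.0)
        assert abs(_rms(out10.data[sl]) / _rms(_sine_rec(10.0).data[sl]) - 1) < 0.05

    def test_notch_preserves_dc(self):
        rec = RawRecording(np.full((1, 2000), 3.7), 250.0, ["C1"], ["EEG"])
        out = mc.notch_filter(rec, 50.0)
        assert np.abs(out.data - 3.7).max() < 1e-6

    def test_notch_rejects_super_nyquist(self):
        with pytest.raises(ValueError):
            mc.notch_filter(_sine_rec(10.0), 130.0)

    @pytest.mark.parametrize("freq, band, min_db_drop, keep", [
        (2.0, (8.0, 30.0), 20.0, False),    # stopband >= 20 dB down
        (15.0, (8.0, 30.0), None, True),    # passband within 10 %
    ])
    def test_bandpass_response(self, freq, band, min_db_drop, keep):
        rec = _sine_rec(freq)
        out = mc.bandpass_filter(rec, *band)
        ratio = _rms(out.data[:, 500:-500]) / _rms(rec.data[:, 500:-500])
        if keep:
            assert abs(ratio - 1) < 0.10
        else:
            assert 20 * np.log10(ratio) < -min_db_drop

    def test_bandpass_limits_spectral_mass(self):
        rng = np.random.default_rng(0)
        rec = RawRecording(rng.standard_normal((1, 50000)), 250.0,
                           ["C1"], ["EEG"])
        out = mc.bandpass_filter(rec, 8.0, 30.0)
        from scipy.signal import periodogram
        f, p = periodogram(out.data[0], fs=250.0)
        outside = p[(f < 8.0) | (f > 30.0)].sum()
        assert outside / p.sum() < 0.10

    def test_bandpass_rejects_inverted_band(self):
        with pytest.raises(ValueError):
            mc.bandpass_filter(_sine_rec(10.0), 30.0, 8.0)

    def test_filters_are_zero_phase(self):
        # a band-limited burst keeps its cross-correlation peak at lag 0
        fs, n = 250.0, 4000
        t = np.arange(n) / fs
        burst = np.sin(2 * np.pi * 15.0 * t) * np.exp(-0.5 * ((t - 8.0) / 0.5) ** 2)
        rec = RawRecording(burst[None, :], fs, ["C1"], ["EEG"])
        out = mc.bandpass_filter(rec, 8.0, 30.0).data[0]
        lags = np.arange(-50, 51)
        cc = [np.dot(burst[50:-50], out[50 + L:n - 50 + L]) for L in lags]
        assert lags[int(np.argmax(cc))] == 0


class TestXcorr:
    @pytest.mark.parametrize("x, y, expected", [
        ([1.0, 2.0, 5.0, 3.0], [1.0, 2.0, 5.0, 3.0], 1.0),
        ([1.0, 2.0, 5.0, 3.0], [-1.0, -2.0, -5.0, -3.0], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),      # hand computation
    ])
    def test_known_values(self, x, y, expected):
        assert mc.xcorr(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateSignalError):
            mc.xcorr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSobi:
    def _mixed_ar_recording(self, seed, n=20000):
        rng = np.random.default_rng(seed)
        S = np.stack([ar1(n, a, rng) for a in (0.9, 0.5, -0.7)])
        A = rng.standard_normal((3, 3))
        rec = RawRecording(A @ S, 250.0, ["a", "b", "c"], ["EEG"] * 3)
        return rec, A

    def test_recovers_ar_sources(self):
        rec, A = self._mixed_ar_recording(0)
        dec = sobi(rec, n_lags=100)
        assert amari_index(dec.unmixing @ A) < 0.1

    def test_amari_invariant_to_component_relabeling(self):
        rec, A = self._mixed_ar_recording(1)
        dec = sobi(rec, n_lags=100)
        P = dec.unmixing @ A
        perm = P[[2, 0, 1]] * np.array([[1.0], [-1.0], [1.0]])
        assert amari_index(perm) == pytest.approx(amari_index(P), abs=1e-12)

    def test_identity_mixing_gives_signed_permutation(self):
        rng = np.random.default_rng(2)
        S = np.stack([ar1(20000, a, rng) for a in (0.95, 0.6, -0.8)])
        rec = RawRecording(S, 250.0, ["a", "b", "c"], ["EEG"] * 3)
        dec = sobi(rec, n_lags=100)
        assert amari_index(dec.unmixing) < 0.1

    def test_iid_white_sources_flagged_low_confidence(self):
        rng = np.random.default_rng(3)
        rec = RawRecording(rng.standard_normal((3, 20000)), 250.0,
                           ["a", "b", "c"], ["EEG"] * 3)
        with pytest.warns(RuntimeWarning, match="temporal structure"):
            dec = sobi(rec, n_lags=50)
        assert dec.low_confidence

    def test_reconstruction_identity_without_flags(self):
        rec, _ = self._mixed_ar_recording(4, n=5000)
        dec = sobi(rec, n_lags=50)
        X = rec.data - rec.data.mean(axis=1, keepdims=True)
        resid = np.linalg.norm(dec.mixing @ dec.sources - X)
        assert resid / np.linalg.norm(X) < 1e-6

    def test_unmixing_mixing_identity(self):
        rec, _ = self._mixed_ar_recording(5, n=5000)
        dec = sobi(rec, n_lags=50)
        assert np.allclose(dec.unmixing @ dec.mixing, np.eye(3), atol=1e-8)


class TestFlagAndZero:
    def test_blink_component_flagged_and_removed(self, small_recording):
        rec, truth = small_recording
        cleaned, dec = mc.denoise(rec)
        assert dec.artifact_flags.sum() >= 1
        frontal = [i for i, l in enumerate(rec.channel_labels)
                   if l.startswith("F")]
        worst = max(abs(xcorr(cleaned.data[i], cleaned.data[j]))
                    for i in frontal for j in cleaned.eog_indices)
        assert worst < 0.2

    def test_threshold_near_one_changes_nothing(self, small_recording):
        rec, _ = small_recording
        filt = mc.notch_filter(rec)
        dec = sobi(filt)
        flagged, cleaned = flag_and_zero(dec, filt, threshold=0.999999)
        assert not flagged.artifact_flags.any()
        eeg = filt.data[filt.eeg_indices]
        assert np.abs(cleaned.data[filt.eeg_indices] - eeg).max() \
            < 1e-6 * np.abs(eeg).max()

    def test_flags_monotone_in_threshold(self, small_recording):
        rec, _ = small_recording
        filt = mc.notch_filter(rec)
        dec = sobi(filt)
        flags = {}
        for thr in (0.7, 0.5, 0.3):
            f, _ = flag_and_zero(dec, filt, threshold=thr)
            flags[thr] = f.artifact_flags
        assert (flags[0.5] | flags[0.7]).sum() == flags[0.5].sum()
        assert (flags[0.3] | flags[0.5]).sum() == flags[0.3].sum()

    def test_no_eog_channels_rejected(self):
        rng = np.random.default_rng(0)
        S = np.stack([ar1(5000, a, rng) for a in (0.9, 0.5, -0.7)])
        rec = RawRecording(S, 250.0, ["a", "b", "c"], ["EEG"] * 3)
        dec = sobi(rec, n_lags=20)
        with pytest.raises(ValueError, match="EOG"):
            flag_and_zero(dec, rec, threshold=0.5)

    def test_refuses_to_zero_everything(self):
        # every source is a near-copy of the EOG signal -> all flagged
        rng = np.random.default_rng(1)
        base = ar1(5000, 0.9, rng)
        sources = np.stack([base + 0.01 * ar1(5000, 0.5, rng)
                            for _ in range(3)])
        data = np.vstack([sources, base[None, :]])
        rec = RawRecording(data, 250.0, ["a", "b", "c", "eog"],
                           ["EEG"] * 3 + ["EOG"])
        dec = mc.ICDecomposition(mixing=np.eye(3), unmixing=np.eye(3),
                                 sources=sources,
                                 channel_indices=np.arange(3))
        with pytest.raises(RuntimeError, match="refusing"):
            flag_and_zero(dec, rec, threshold=0.5)

    def test_scores_lie_in_unit_interval(self, small_recording):
        rec, _ = small_recording
        dec = sobi(mc.notch_filter(rec))
        scores = score_components(dec, rec.data[rec.eog_indices])
        assert (scores >= 0).all() and (scores <= 1).all()
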