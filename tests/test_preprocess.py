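"""Conditioning chain: normalization conventions, filter response,
artifact handling."""

import numpy as np
import pytest

from nbackeeg.core import CHANNELS, EEGRecording
from nbackeeg.preprocess import (
    CleaningReport,
    bandpass,
    clean_artifacts,
    normalize,
    preprocess_chain,
)
from nbackeeg.synthetic import ConditionSpec, StudySpec, generate_recording

FS = 250.0


def make_recording(data):
    return EEGRecording(data=data, sample_rate_hz=FS)


def uniform_spec():
    return ConditionSpec("am", {ch: np.full(6, 1 / 6) for ch in CHANNELS})


class TestNormalize:
    def test_two_point_population_convention(self):
        data = np.tile([1.0, 3.0], (8, 1))
        out = normalize(make_recording(data))
        assert np.allclose(out.data, np.tile([-1.0, 1.0], (8, 1)))

    def test_moments(self, rng):
        out = normalize(make_recording(rng.normal(3, 7, size=(8, 1000))))
        assert np.allclose(out.data.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(out.data.var(axis=1), 1, atol=1e-9)

    def test_idempotent(self, rng):
        once = normalize(make_recording(rng.normal(size=(8, 500))))
        twice = normalize(once)
        assert np.allclose(once.data, twice.data, atol=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(8, 400))
        a, b = 3.7, -12.0
        assert np.allclose(
            normalize(make_recording(x)).data,
            normalize(make_recording(a * x + b)).data,
            atol=1e-9,
        )

    def test_constant_channel_named(self):
        data = np.random.default_rng(0).normal(size=(8, 100))
        data[CHANNELS.index("T5")] = 2.0
        with pytest.raises(ValueError, match="T5"):
            normalize(make_recording(data))


class TestBandpass:
    def probe(self, freq, n=5000):
        t = np.arange(n) / FS
        sig = np.tile(np.sin(2 * np.pi * freq * t), (8, 1))
        out = bandpass(make_recording(sig))
        mid = slice(n // 4, 3 * n // 4)  # avoid edge transients
        return np.abs(out.data[0, mid]).max()

    def test_passband_tone_preserved(self):
        assert self.probe(10.0) == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_rejected(self):
        assert self.probe(0.2) < 0.1

    def test_dc_rejected(self):
        out = bandpass(make_recording(np.ones((8, 2000))))
        assert np.abs(out.data).max() < 1e-6

    def test_stopband_attenuation(self):
        # >= 20 dB (x0.1 amplitude) at 0.5 Hz and at 80 Hz
        assert self.probe(0.5, n=20000) < 0.1
        assert self.probe(80.0) < 0.1

    def test_passband_flat_in_core(self):
        # < 1 dB over 4-40 Hz; the 45-50 Hz shoulder rolls off earlier,
        # an accepted property of the 4th-order Butterworth edge
        for f in (4.0, 10.0, 25.0, 40.0):
            assert self.probe(f) == pytest.approx(1.0, abs=0.12)

    def test_invalid_edges(self):
        with pytest.raises(ValueError, match="band edges"):
            bandpass(make_recording(np.random.default_rng(0).normal(size=(8, 100))), 50, 2)


class TestCleanArtifacts:
    def test_blink_free_null_case(self):
        rec = generate_recording(uniform_spec(), StudySpec(blink_rate_hz=0.0), seed=0)
        rec = bandpass(normalize(rec))
        cleaned, report = clean_artifacts(rec, seed=0)
        assert report.n_components_removed == 0
        assert report.excised_windows_s == []
        assert report.fraction_excised == 0.0

    @staticmethod
    def peak_over_background(x):
        """Peak amplitude in units of the channel's robust (median
        absolute deviation) background scale - comparable across the
        unit change that normalization introduces."""
        mad = np.median(np.abs(x - np.median(x)))
        return np.abs(x).max() / (mad / 0.6745)

    @pytest.mark.parametrize("seed", [2, 6])
    def test_injected_blinks_reduced(self, seed):
        """After the full chain (filtering, ICA, and excision of flagged
        windows), the retained frontal signal's peak shrinks by >= 50%
        relative to the background scale of the uncleaned signal."""
        rec = generate_recording(uniform_spec(), StudySpec(blink_rate_hz=0.5), seed=seed)
        before = self.peak_over_background(rec.channel("Fp1"))
        cleaned = preprocess_chain(rec)
        fs = rec.sample_rate_hz
        keep = np.ones(rec.n_samples, dtype=bool)
        for a, b in cleaned.report.excised_windows_s:
            keep[int(a * fs) : int(b * fs) + 1] = False
        x = cleaned.recording.channel("Fp1")
        mad = np.median(np.abs(x - np.median(x))) / 0.6745
        after = np.abs(x[keep]).max() / mad
        assert after < 0.5 * before

    def test_shape_rate_length_preserved(self):
        rec = generate_recording(uniform_spec(), StudySpec(blink_rate_hz=0.3), seed=1)
        out = preprocess_chain(rec)
        assert out.recording.data.shape == rec.data.shape
        assert out.recording.sample_rate_hz == rec.sample_rate_hz

    def test_excised_windows_sorted_nonoverlapping(self):
        rec = generate_recording(uniform_spec(), StudySpec(blink_rate_hz=1.0), seed=3)
        out = preprocess_chain(rec)
        windows = out.report.excised_windows_s
        for (a0, b0), (a1, b1) in zip(windows, windows[1:]):
            assert b0 <= a1
        assert 0.0 <= out.report.fraction_excised <= 1.0

    def test_deterministic_under_seed(self):
        rec = generate_recording(uniform_spec(), StudySpec(blink_rate_hz=0.3), seed=8)
        a = preprocess_chain(rec)
        b = preprocess_chain(rec)
        assert np.array_equal(a.recording.data, b.recording.data)
        assert a.report.excised_windows_s == b.report.excised_windows_s

    def test_blink_free_chain_matches_normalize_bandpass(self):
        """On blink-free input the full chain equals normalize+bandpass
        up to numerical tolerance (ICA either converges to a rotation it
        undoes, or passes through)."""
        rec = generate_recording(uniform_spec(), StudySpec(blink_rate_hz=0.0), seed=9)
        plain = bandpass(normalize(rec))
        chained = preprocess_chain(rec)
        assert np.allclose(chained.recording.data, plain.data, atol=1e-6)


def test_cleaning_report_validation():
    with pytest.raises(ValueError):
        CleaningReport(fraction_excised=1.5)
    with pytest.raises(ValueError, match="sorted"):
        CleaningReport(excised_windows_s=[(2.0, 3.0), (1.0, 1.5)])
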