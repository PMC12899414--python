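"""Feature-layer oracles: band powers, relative power, compacted
waveforms, window bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbackeeg.core import BandSpec, CANONICAL_BANDS, CHANNELS, EEGRecording
from nbackeeg.features import (
    band_powers,
    build_dataset,
    compact_waveform,
    epoch_relative_power,
    relative_power,
    window_starts,
)
from nbackeeg.preprocess import CleanedRecording, CleaningReport

FS = 250.0


def tone(freq, n=250, amp=1.0):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def make_recording(data, **kw):
    return EEGRecording(data=data, sample_rate_hz=FS, **kw)


class TestBandPowers:
    def test_pure_alpha_tone(self):
        p = band_powers(tone(10.0)[None, :])
        assert p[0, 2] / p.sum() > 0.99  # alpha row

    def test_two_tone_symmetry(self):
        p = band_powers((tone(5.0) + tone(20.0))[None, :])[0]
        total = p.sum()
        assert p[1] == pytest.approx(0.5 * total, rel=0.01)  # theta
        assert p[4] == pytest.approx(0.5 * total, rel=0.01)  # beta2

    def test_parseval(self, rng):
        """Band powers plus out-of-band power reproduce the signal energy."""
        x = rng.normal(size=(3, 250))
        in_band = band_powers(x).sum(axis=1)
        rest = band_powers(
            x, bands=[BandSpec("lo", 1e-12, 2.0), BandSpec("hi", 50.0, 126.0)]
        ).sum(axis=1)
        dc = np.abs(x.mean(axis=1)) ** 2 * x.shape[1]
        energy = (x**2).sum(axis=1)
        assert np.allclose(in_band + rest + dc, energy, rtol=1e-6)

    def test_rejects_short_window(self):
        with pytest.raises(ValueError):
            band_powers(np.ones((1, 1)))


class TestRelativePower:
    def test_uniform_and_arithmetic(self):
        assert np.allclose(relative_power(np.ones((1, 6))), 1 / 6)
        out = relative_power(np.array([[0.0, 3, 0, 0, 0, 1]]))
        assert np.allclose(out, [[0, 0.75, 0, 0, 0, 0.25]])

    def test_scale_invariance(self, rng):
        p = rng.random((4, 6)) + 0.1
        assert np.allclose(relative_power(p), relative_power(37.5 * p))

    def test_all_zero_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            relative_power(np.zeros((1, 6)))

    def test_simplex_invariant(self, rng):
        out = relative_power(rng.random((8, 6)) + 1e-6)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert (out >= 0).all()


class TestCompactWaveform:
    def test_constant(self):
        assert np.allclose(compact_waveform(np.full((2, 250), 3.5)), 3.5)

    def test_ramp_exact(self):
        """Brute-force averaging over the (4,4,4,4,4,5) index sets."""
        out = compact_waveform(np.arange(250.0)[None, :])[0]
        assert np.allclose(out, [114.0, 118.0, 122.0, 126.0, 130.0, 134.5])

    def test_block_periodic_signal(self):
        """A 10 Hz sine has period 25 = one block, so the block average
        equals the segment means of a single cycle."""
        x = tone(10.0)
        out = compact_waveform(x[None, :])[0]
        cycle = x[:25]
        expected = [
            cycle[0:4].mean(), cycle[4:8].mean(), cycle[8:12].mean(),
            cycle[12:16].mean(), cycle[16:20].mean(), cycle[20:25].mean(),
        ]
        assert np.allclose(out, expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 2**16))
    def test_linearity(self, a, b, seed):
        g = np.random.default_rng(seed)
        x, y = g.normal(size=(2, 1, 250))
        assert np.allclose(
            compact_waveform(a * x + b * y),
            a * compact_waveform(x) + b * compact_waveform(y),
            atol=1e-9,
        )

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError, match="250"):
            compact_waveform(np.zeros((1, 200)))


class TestWindowing:
    def test_111_starts(self):
        starts = window_starts((3.0, 15.0), 0.1, 1.0)
        assert len(starts) == 111
        assert starts[0] == pytest.approx(3.0) and starts[-1] == pytest.approx(14.0)

    def test_count_formula_other_grids(self):
        assert len(window_starts((0.0, 10.0), 0.5, 1.0)) == 19

    def test_dataset_count_and_labels(self, rng):
        recs = [
            make_recording(
                rng.normal(size=(8, 4000)), session_label=lbl, participant_id="P1"
            )
            for lbl in ("am", "pm")
        ]
        ex = build_dataset(recs, "relative_power")
        assert len(ex) == 2 * 111
        assert {e.label for e in ex} == {0, 1}

    def test_excised_interval_drops_open_overlap(self, rng):
        """An excised 5-6 s interval removes exactly the windows whose
        start lies in the open interval (4.0, 6.0)."""
        rec = make_recording(rng.normal(size=(8, 4000)), session_label="am")
        cleaned = CleanedRecording(
            rec, CleaningReport(excised_windows_s=[(5.0, 6.0)], fraction_excised=1 / 16)
        )
        ex = build_dataset([cleaned], "relative_power")
        kept = {round(e.start_s, 1) for e in ex}
        dropped = {round(0.1 * k, 1) for k in range(41, 60)}  # (4.0, 6.0) open
        assert kept.isdisjoint(dropped)
        assert 4.0 in kept and 6.0 in kept
        assert len(ex) == 111 - len(dropped)

    def test_raw_representation_shape(self, rng):
        rec = make_recording(rng.normal(size=(8, 4000)), session_label="pm")
        ex = build_dataset([rec], "raw_waveform")
        assert ex[0].features.shape == (8, 6)

    def test_unknown_representation(self):
        with pytest.raises(ValueError, match="representation"):
            build_dataset([], "wavelet")


class TestEpochRelativePower:
    def test_pure_alpha_everywhere(self):
        data = np.tile(tone(10.0, n=4000), (8, 1))
        rp = epoch_relative_power(make_recording(data))
        assert (rp[:, 2] > 0.95).all()

    def test_locality(self, rng):
        data = rng.normal(size=(8, 4000))
        rec = make_recording(data)
        rp0 = epoch_relative_power(rec, (5.0, 15.0))
        tampered = data.copy()
        tampered[:, : int(5 * FS)] = 999.0
        tampered[:, int(15 * FS) :] = -999.0
        rp1 = epoch_relative_power(make_recording(tampered), (5.0, 15.0))
        assert np.array_equal(rp0, rp1)

    def test_epoch_beyond_recording(self, rng):
        rec = make_recording(rng.normal(size=(8, 1000)))
        with pytest.raises(ValueError, match="exceeds"):
            epoch_relative_power(rec, (5.0, 15.0))
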