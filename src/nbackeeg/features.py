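"""Feature extraction: six-band powers, relative power, compacted
waveforms, and the sliding-window dataset.

Two 8x6 representations feed the classifier:

* relative power - per channel, the FFT squared-magnitude spectrum of a
  1-s window summed over each band's half-open [low, high) bins and
  normalized to fractions (a point on the 5-simplex per channel);
* compacted waveform - the 250-sample window split into 10 blocks of 25
  samples, each block into six segments of (4,4,4,4,4,5) samples, and
  segment means averaged across the blocks, giving six values per
  channel.  The map is linear in the signal.

Windows slide at 0.1 s steps with starts from 3.0 to 14.0 s after task
onset (111 per artifact-free recording); windows overlapping an excised
interval are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BAND_NAMES, CANONICAL_BANDS, CHANNELS, N_BANDS, BandSpec, EEGRecording
from .preprocess import CleanedRecording

__all__ = [
    "LabeledExample",
    "band_powers",
    "relative_power",
    "compact_waveform",
    "window_starts",
    "extract_window",
    "build_dataset",
    "epoch_relative_power",
    "stack_examples",
    "examples_to_frame",
    "SEGMENT_PATTERN",
]

#: Within-block segment sizes; the odd 5-sample segment sits last.
SEGMENT_PATTERN: tuple[int, ...] = (4, 4, 4, 4, 4, 5)
_N_BLOCKS = 10
_BLOCK_LEN = 25


@dataclass
class LabeledExample:
    """One 8x6 feature matrix with its class label and provenance."""

    features: np.ndarray  # (8 channels, 6 values)
    label: int
    participant_id: str
    session_label: str
    task_n: int
    trial_index: int
    start_s: float
    representation: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(CHANNELS), N_BANDS):
            raise ValueError(f"features must be 8x6, got {self.features.shape}")


def band_powers(
    window: np.ndarray,
    sample_rate_hz: float = 250.0,
    bands: Sequence[BandSpec] = CANONICAL_BANDS,
) -> np.ndarray:
    """Absolute band powers of a (channels, samples) window.

    The spectrum is the untapered (rectangular-window) one-sided FFT
    periodogram, scaled so the sum over all bins equals the time-domain
    signal energy (Parseval); each band sums the bins with frequency in
    [low, high), so shared edges at 4/8/12/15/30 Hz are never
    double-counted.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n = window.shape[1]
    if n < 2:
        raise ValueError("window too short")
    spec = np.abs(np.fft.rfft(window, axis=1)) ** 2
    # one-sided energy weights: interior bins count twice
    weights = np.full(spec.shape[1], 2.0 / n)
    weights[0] = 1.0 / n
    if n % 2 == 0:
        weights[-1] = 1.0 / n
    spec = spec * weights
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    out = np.empty((window.shape[0], len(bands)))
    for bi, b in enumerate(bands):
        mask = (freqs >= b.low_hz) & (freqs < b.high_hz)
        out[:, bi] = spec[:, mask].sum(axis=1)
    return out


def relative_power(powers: np.ndarray) -> np.ndarray:
    """Normalize per-channel band powers to fractions summing to 1."""
    powers = np.atleast_2d(np.asarray(powers, dtype=float))
    totals = powers.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("all-zero band powers; cannot form relative power")
    return powers / totals


def compact_waveform(window: np.ndarray) -> np.ndarray:
    """Block-averaged six-value summary of a (channels, 250) window.

    Linear in the input: compact(a*x + b*y) = a*compact(x) + b*compact(y).
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n_expected = _N_BLOCKS * _BLOCK_LEN
    if window.shape[1] != n_expected:
        raise ValueError(f"window must have {n_expected} samples, got {window.shape[1]}")
    blocks = window.reshape(window.shape[0], _N_BLOCKS, _BLOCK_LEN)
    out = np.empty((window.shape[0], len(SEGMENT_PATTERN)))
    pos = 0
    for k, size in enumerate(SEGMENT_PATTERN):
        out[:, k] = blocks[:, :, pos : pos + size].mean(axis=2).mean(axis=1)
        pos += size
    return out


def window_starts(
    crop: tuple[float, float] = (3.0, 15.0),
    step: float = 0.1,
    window_s: float = 1.0,
) -> np.ndarray:
    """Window start offsets: crop[0], crop[0]+step, ..., crop[1]-window_s.

    For the defaults this is 3.0, 3.1, ..., 14.0 s - 111 windows, so
    every window lies inside the crop range.
    """
    lo, hi = crop
    last = hi - window_s
    n = int(round((last - lo) / step)) + 1
    if n < 1:
        raise ValueError(f"crop {crop} cannot hold a {window_s} s window")
    return lo + step * np.arange(n)


def extract_window(
    recording: EEGRecording, start_s: float, window_s: float = 1.0
) -> np.ndarray:
    """(channels, samples) slice at ``start_s`` after task onset."""
    fs = recording.sample_rate_hz
    i0 = int(round((recording.task_start_s + start_s) * fs))
    i1 = i0 + int(round(window_s * fs))
    if i0 < 0 or i1 > recording.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + window_s}] s exceeds the recording"
        )
    return recording.data[:, i0:i1]


def _overlaps(start: float, window_s: float, interval: tuple[float, float]) -> bool:
    a, b = interval
    return (start < b - 1e-9) and (start + window_s > a + 1e-9)


def _default_label_fn(rec: EEGRecording) -> int | None:
    return {"am": 0, "pm": 1, "low": 0, "high": 1}.get(rec.session_label)


def build_dataset(
    recordings: Iterable[EEGRecording | CleanedRecording],
    representation: str = "relative_power",
    crop: tuple[float, float] = (3.0, 15.0),
    step: float = 0.1,
    window_s: float = 1.0,
    label_fn: Callable[[EEGRecording], int | None] | None = None,
) -> list[LabeledExample]:
    """Slide windows over preprocessed recordings and featurize each one.

    ``representation`` is ``"relative_power"`` or ``"raw_waveform"``
    (the compacted-waveform summary).  Windows overlapping an excised
    interval (from a :class:`CleanedRecording` report) are dropped.
    ``label_fn`` maps a recording to its class (default: am/low -> 0,
    pm/high -> 1); returning ``None`` drops the recording.
    """
    if representation not in ("relative_power", "raw_waveform"):
        raise ValueError(f"unknown representation {representation!r}")
    label_fn = label_fn or _default_label_fn
    starts = window_starts(crop, step, window_s)
    examples: list[LabeledExample] = []
    for item in recordings:
        if isinstance(item, CleanedRecording):
            rec, excised = item.recording, item.report.excised_windows_s
        else:
            rec, excised = item, []
        label = label_fn(rec)
        if label is None:
            continue
        for s in starts:
            if any(_overlaps(s, window_s, iv) for iv in excised):
                continue
            w = extract_window(rec, float(s), window_s)
            if representation == "relative_power":
                feats = relative_power(band_powers(w, rec.sample_rate_hz))
            else:
                feats = compact_waveform(w)
            examples.append(
                LabeledExample(
                    features=feats,
                    label=int(label),
                    participant_id=rec.participant_id,
                    session_label=rec.session_label,
                    task_n=rec.task_n,
                    trial_index=rec.trial_index,
                    start_s=float(s),
                    representation=representation,
                )
            )
    return examples


def epoch_relative_power(
    recording: EEGRecording, epoch: tuple[float, float] = (5.0, 15.0)
) -> np.ndarray:
    """Relative power over one long analysis epoch (default 5-15 s after
    task onset), used for condition-level band-power comparisons."""
    lo, hi = epoch
    if hi <= lo:
        raise ValueError("epoch end must exceed start")
    w = extract_window(recording, lo, hi - lo)
    return relative_power(band_powers(w, recording.sample_rate_hz))


def stack_examples(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, participants): X is (n, 8, 6), y int labels, participants str."""
    X = np.stack([e.features for e in examples])
    y = np.array([e.label for e in examples], dtype=int)
    pid = np.array([e.participant_id for e in examples])
    return X, y, pid


def examples_to_frame(examples: Sequence[LabeledExample]) -> pd.DataFrame:
    """Flat CSV-ready table: provenance columns plus 48 feature values."""
    rows = []
    for e in examples:
        row = {
            "participant": e.participant_id,
            "session": e.session_label,
            "task_n": e.task_n,
            "trial": e.trial_index,
            "start_s": e.start_s,
            "representation": e.representation,
            "label": e.label,
        }
        for ci, ch in enumerate(CHANNELS):
            for bi, band in enumerate(BAND_NAMES):
                row[f"{ch}_{band}"] = e.features[ci, bi]
        rows.append(row)
    return pd.DataFrame(rows)
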