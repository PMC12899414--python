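"""Shared domain objects.

The montage is the eight-electrode 10-20 subset Fp1/Fp2/C3/C4/T5/T6/O1/O2
sampled at 250 Hz, and the spectral vocabulary is six contiguous bands
tiling 2-50 Hz: delta (2-4), theta (4-8), alpha (8-12), beta1 (12-15),
beta2 (15-30) and gamma (30-50 Hz).  Everything downstream (synthesis,
preprocessing, features, classification) speaks in these terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Fixed channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "C3", "C4", "T5", "T6", "O1", "O2")

#: Channels that carry ocular (blink) artifacts.
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2")

DEFAULT_SAMPLE_RATE_HZ = 250.0


@dataclass(frozen=True)
class BandSpec:
    """A half-open frequency band [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: low_hz ({self.low_hz}) must be < high_hz ({self.high_hz})"
            )

    @property
    def bandwidth_hz(self) -> float:
        return self.high_hz - self.low_hz


#: The six canonical bands; they tile [2, 50) without overlap.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 2.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta1", 12.0, 15.0),
    BandSpec("beta2", 15.0, 30.0),
    BandSpec("gamma", 30.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
N_BANDS = len(CANONICAL_BANDS)


@dataclass
class EEGRecording:
    """A labeled multichannel EEG time series.

    ``data`` is channels x samples in microvolts, rows ordered as
    ``channel_labels``.  ``task_start_s`` is the offset of task onset
    within the recording; window/epoch times downstream are relative
    to it.
    """

    data: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    channel_labels: tuple[str, ...] = CHANNELS
    participant_id: str = "P1"
    session_label: str = ""
    task_n: int = 2
    trial_index: int = 1
    task_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data must be (n_channels={len(self.channel_labels)}, n_samples); "
                f"got shape {self.data.shape}"
            )
        if set(self.channel_labels) != set(CHANNELS):
            raise ValueError(f"channel_labels must be exactly {set(CHANNELS)}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.task_n not in (2, 3):
            raise ValueError("task_n must be 2 or 3")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        """1-D view of one channel by 10-20 label."""
        return self.data[self.channel_labels.index(name)]

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of this recording with ``data`` replaced (metadata kept)."""
        return replace(self, data=np.asarray(data, dtype=float))

    @property
    def key(self) -> tuple[str, str, int, int]:
        """(participant, session, task, trial) identity tuple."""
        return (self.participant_id, self.session_label, self.task_n, self.trial_index)


def band_index(name: str) -> int:
    return BAND_NAMES.index(name)


def validate_fractions(frac: Sequence[float], *, what: str = "band fractions") -> np.ndarray:
    """Check a 6-vector lies on the simplex (sum 1 within 1e-9, all >= 0)."""
    arr = np.asarray(frac, dtype=float)
    if arr.shape != (N_BANDS,):
        raise ValueError(f"{what}: expected {N_BANDS} values, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"{what}: fractions must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what}: fractions must sum to 1 (got {arr.sum()!r})")
    return arr
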