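"""Synthetic band-structured EEG and behavioral data.

The generator emulates the statistical structure the analysis assumes,
not physiology: each channel is a sum over the six canonical bands of
independent Gaussian noise confined to that band, with per-band variances
chosen so the *measured* relative power (as computed by the features
module's FFT band-sum estimator) matches a target fraction vector.  Band
confinement uses brick-wall FFT masks over exactly the half-open
[low, high) bins the features module sums, so target and measurement are
self-consistent by construction.

Condition differences (e.g. morning vs afternoon) enter through the
target fractions; inter-participant variability enters as a per-subject
offset applied on the logit of the fractions and renormalized, keeping
fractions in (0, 1).  Blink artifacts are raised-cosine transients
(>=100 uV, 300-500 ms, spectral content below ~3 Hz) superposed on
Fp1/Fp2, so the 2-50 Hz band-pass stage demonstrably removes most of
their energy.  Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BAND_NAMES,
    CANONICAL_BANDS,
    CHANNELS,
    FRONTAL_CHANNELS,
    N_BANDS,
    EEGRecording,
    validate_fractions,
)
from .study_tables import relative_power_matrix

__all__ = [
    "ConditionSpec",
    "StudySpec",
    "SyntheticStudy",
    "generate_recording",
    "generate_study",
    "generate_behavior_table",
    "table2_condition_specs",
    "flat_spectrum_fractions",
]


@dataclass(frozen=True)
class ConditionSpec:
    """Target per-channel band fractions for one experimental condition."""

    label: str
    channel_band_fractions: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if ch not in self.channel_band_fractions:
                raise ValueError(f"condition {self.label!r}: missing channel {ch}")
            validate_fractions(
                self.channel_band_fractions[ch], what=f"{self.label}/{ch}"
            )

    def fractions(self, channel: str) -> np.ndarray:
        return np.asarray(self.channel_band_fractions[channel], dtype=float)

    @classmethod
    def from_matrix(cls, label: str, matrix: np.ndarray) -> "ConditionSpec":
        """Build from an (8 channels, 6 bands) fraction matrix."""
        matrix = np.asarray(matrix, dtype=float)
        return cls(label, {ch: matrix[i] for i, ch in enumerate(CHANNELS)})


@dataclass(frozen=True)
class StudySpec:
    """Design parameters of a simulated study.

    Defaults mirror the emulated pilot design: 5 participants, each
    condition recorded twice, 250 Hz.  ``subject_sd`` is the standard
    deviation of the per-participant logit-scale band-fraction offset
    (0.3 gives moderate, clearly visible inter-participant variability);
    ``blink_rate_hz`` is the expected blink count per second on the
    frontal channels.
    """

    n_participants: int = 5
    sessions_per_condition: int = 2
    duration_s: float = 16.0
    sample_rate_hz: float = 250.0
    subject_sd: float = 0.3
    blink_rate_hz: float = 0.1
    eeg_rms_uv: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 15.0:
            raise ValueError(
                "duration_s must be >= 15 s to cover the 3-15 s analysis range"
            )
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.n_participants < 1 or self.sessions_per_condition < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticStudy:
    """A bundle of generated recordings plus per-session behavioral tables.

    ``behaviors`` maps a recording's identity tuple
    (participant, session, task, trial) to its 20-trial table.
    """

    recordings: list[EEGRecording]
    behaviors: dict[tuple[str, str, int, int], pd.DataFrame]
    study: StudySpec

    def recordings_for(self, task_n: int) -> list[EEGRecording]:
        return [r for r in self.recordings if r.task_n == task_n]


def _logit_offset_fractions(frac: np.ndarray, offset: np.ndarray | None) -> np.ndarray:
    """Apply an additive offset on the logit of each fraction, renormalize."""
    if offset is None:
        return frac
    frac = np.clip(frac, 1e-12, 1 - 1e-12)
    logit = np.log(frac / (1.0 - frac)) + np.asarray(offset, dtype=float)
    shifted = 1.0 / (1.0 + np.exp(-logit))
    return shifted / shifted.sum()


def _band_mask(n_samples: int, fs: float, low: float, high: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    return (freqs >= low) & (freqs < high)


def _blink_pulse(fs: float, width_s: float, amp_uv: float) -> np.ndarray:
    n = max(int(round(width_s * fs)), 2)
    t = np.arange(n) / (n - 1)
    return amp_uv * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def generate_recording(
    spec: ConditionSpec,
    study: StudySpec,
    participant_offset: np.ndarray | None = None,
    seed: int = 0,
    *,
    participant_id: str = "P1",
    task_n: int = 2,
    trial_index: int = 1,
) -> EEGRecording:
    """Generate one band-structured recording for one condition.

    Each channel is a sum over bands of unit-variance brick-wall
    band-limited Gaussian noise weighted by the square root of the
    (offset-adjusted) target fraction, scaled to ``study.eeg_rms_uv``.
    Blinks are added to Fp1/Fp2 at rate ``study.blink_rate_hz``.
    Identical (spec, study, seed) inputs reproduce the identical
    recording bitwise.
    """
    rng = np.random.default_rng(seed)
    fs = study.sample_rate_hz
    n = int(round(study.duration_s * fs))
    data = np.zeros((len(CHANNELS), n))

    masks = [
        _band_mask(n, fs, b.low_hz, b.high_hz) for b in CANONICAL_BANDS
    ]
    for ci, ch in enumerate(CHANNELS):
        frac = _logit_offset_fractions(spec.fractions(ch), participant_offset)
        sig = np.zeros(n)
        for bi in range(N_BANDS):
            if frac[bi] <= 0:
                # still draw so the stream layout is independent of fractions
                rng.standard_normal(n)
                continue
            white = rng.standard_normal(n)
            spectrum = np.fft.rfft(white)
            spectrum[~masks[bi]] = 0.0
            comp = np.fft.irfft(spectrum, n)
            sd = comp.std()
            if sd > 0:
                sig += np.sqrt(frac[bi]) * comp / sd
        data[ci] = study.eeg_rms_uv * sig

    # Blink transients on the frontal pair.
    n_blinks = rng.poisson(study.blink_rate_hz * study.duration_s)
    for _ in range(n_blinks):
        width = rng.uniform(0.3, 0.5)
        amp = rng.uniform(120.0, 180.0)
        start = rng.uniform(0.0, max(study.duration_s - width, 0.0))
        pulse = _blink_pulse(fs, width, amp)
        i0 = int(round(start * fs))
        i1 = min(i0 + pulse.size, n)
        for ch in FRONTAL_CHANNELS:
            scale = 1.0 if ch == "Fp1" else rng.uniform(0.85, 1.0)
            data[CHANNELS.index(ch), i0:i1] += scale * pulse[: i1 - i0]

    return EEGRecording(
        data=data,
        sample_rate_hz=fs,
        participant_id=participant_id,
        session_label=spec.label,
        task_n=task_n,
        trial_index=trial_index,
        task_start_s=0.0,
    )


#: Default per-condition correct-answer probabilities, matching the
#: group means of the packaged behavioral fixture.
DEFAULT_CORRECT_RATES: dict[tuple[int, str], float] = {
    (2, "am"): 0.80,
    (2, "pm"): 0.885,
    (3, "am"): 0.68,
    (3, "pm"): 0.74,
}

_SHAPES = ("square", "circle", "triangle")


def generate_behavior_table(
    rng: np.random.Generator,
    correct_rate: float,
    n_trials: int = 20,
    rt_log_mean: float = 6.65,  # exp(6.65) ~ 773 ms
    rt_log_sd: float = 0.25,
) -> pd.DataFrame:
    """One 20-trial N-back behavioral table.

    Columns: trial, stimulus, expected, response, correct, rt_ms.
    Correctness is Bernoulli(correct_rate); response times log-normal.
    """
    stimuli = rng.choice(_SHAPES, size=n_trials)
    expected = rng.choice(["same", "other"], size=n_trials)
    correct = rng.random(n_trials) < correct_rate
    response = np.where(
        correct, expected, np.where(expected == "same", "other", "same")
    )
    rt = np.exp(rng.normal(rt_log_mean, rt_log_sd, size=n_trials))
    return pd.DataFrame(
        {
            "trial": np.arange(1, n_trials + 1),
            "stimulus": stimuli,
            "expected": expected,
            "response": response,
            "correct": correct.astype(int),
            "rt_ms": np.round(rt, 1),
        }
    )


def generate_study(
    am_spec: ConditionSpec,
    pm_spec: ConditionSpec,
    study: StudySpec,
    *,
    task_n: int = 2,
    correct_rates: Mapping[str, float] | None = None,
) -> SyntheticStudy:
    """Simulate one task of a two-condition within-subject study.

    Produces ``n_participants x 2 conditions x sessions_per_condition``
    recordings.  Each participant receives one logit-scale offset vector
    (sd ``study.subject_sd``) applied identically to both conditions, so
    subject identity is a nuisance factor orthogonal to condition.
    """
    if set(am_spec.channel_band_fractions) != set(pm_spec.channel_band_fractions):
        raise ValueError("condition specs must share the channel set")
    if correct_rates is None:
        correct_rates = {
            am_spec.label: DEFAULT_CORRECT_RATES.get((task_n, am_spec.label), 0.75),
            pm_spec.label: DEFAULT_CORRECT_RATES.get((task_n, pm_spec.label), 0.80),
        }
    master = np.random.default_rng(study.seed)
    recordings: list[EEGRecording] = []
    behaviors: dict[tuple[str, str, int, int], pd.DataFrame] = {}
    for p in range(1, study.n_participants + 1):
        pid = f"P{p}"
        offset = (
            master.normal(0.0, study.subject_sd, size=N_BANDS)
            if study.subject_sd > 0
            else np.zeros(N_BANDS)
        )
        for spec in (am_spec, pm_spec):
            for trial in range(1, study.sessions_per_condition + 1):
                rec_seed = int(master.integers(2**31))
                rec = generate_recording(
                    spec,
                    study,
                    participant_offset=offset,
                    seed=rec_seed,
                    participant_id=pid,
                    task_n=task_n,
                    trial_index=trial,
                )
                recordings.append(rec)
                behaviors[rec.key] = generate_behavior_table(
                    master, correct_rates[spec.label]
                )
    return SyntheticStudy(recordings=recordings, behaviors=behaviors, study=study)


def table2_condition_specs(task_n: int) -> tuple[ConditionSpec, ConditionSpec]:
    """(am, pm) condition specs parameterized from the published
    group-mean relative powers for the given task."""
    am = ConditionSpec.from_matrix("am", relative_power_matrix(task_n, "am"))
    pm = ConditionSpec.from_matrix("pm", relative_power_matrix(task_n, "pm"))
    return am, pm


def flat_spectrum_fractions() -> np.ndarray:
    """Band fractions of a spectrum with equal power density over 2-50 Hz:
    each band's fraction is bandwidth / 48."""
    widths = np.array([b.bandwidth_hz for b in CANONICAL_BANDS])
    return widths / widths.sum()
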