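"""File formats: OpenBCI GUI TXT recordings, study manifests, run config.

The TXT dialect matches OpenBCI GUI v5/v6 exports: '%'-prefixed header
lines (one of which states the sample rate), an optional column-name
line, then comma-separated rows whose first column is a sample counter
followed by the eight channel values in microvolts.  Accessory columns
(aux, timestamp, ...) beyond channel 8 are tolerated and ignored.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import CHANNELS, DEFAULT_SAMPLE_RATE_HZ, EEGRecording
from .study_tables import table1_frame

logger = logging.getLogger(__name__)

__all__ = [
    "read_openbci_txt",
    "write_openbci_txt",
    "StudyManifest",
    "ManifestEntry",
    "write_study",
    "load_study",
    "load_table1_fixture",
    "RunConfig",
]

_SAMPLE_RATE_RE = re.compile(r"sample\s*rate\s*=?\s*([0-9.]+)", re.IGNORECASE)


def read_openbci_txt(path: str | Path, **metadata) -> EEGRecording:
    """Parse an OpenBCI GUI TXT export into an :class:`EEGRecording`.

    Header lines beginning with '%' are skipped (the sample rate is read
    from the one containing "Sample Rate", defaulting to 250 Hz); a
    non-numeric column-name line is tolerated.  Keyword arguments
    (participant_id, session_label, ...) populate the recording metadata.
    A non-monotone sample index is logged as a warning but rows are kept.
    """
    path = Path(path)
    sample_rate = DEFAULT_SAMPLE_RATE_HZ
    rows: list[list[float]] = []
    indices: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("%"):
                m = _SAMPLE_RATE_RE.search(line)
                if m:
                    sample_rate = float(m.group(1))
                continue
            fields = [f.strip() for f in line.split(",")]
            try:
                values = [float(f) for f in fields]
            except ValueError:
                # column-name line (only tolerated before any data)
                if not rows:
                    continue
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric data row: {line!r}"
                )
            if len(values) < 1 + len(CHANNELS):
                raise ValueError(
                    f"{path.name}:{lineno}: expected at least "
                    f"{1 + len(CHANNELS)} columns, got {len(values)}"
                )
            indices.append(values[0])
            rows.append(values[1 : 1 + len(CHANNELS)])
    if not rows:
        raise ValueError(f"{path.name}: no samples")
    idx = np.asarray(indices)
    if np.any(np.diff(idx) < 0):
        logger.warning("%s: non-monotone sample index; rows kept as read", path.name)
    data = np.asarray(rows).T
    return EEGRecording(data=data, sample_rate_hz=sample_rate, **metadata)


def write_openbci_txt(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording in the OpenBCI GUI TXT dialect (6 significant
    digits, microvolt scale)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("%OpenBCI Raw EEG Data\n")
        fh.write(f"%Number of channels = {recording.n_channels}\n")
        fh.write(f"%Sample Rate = {recording.sample_rate_hz:g} Hz\n")
        fh.write("%Board = SyntheticCyton\n")
        fh.write(
            "Sample Index, "
            + ", ".join(f"EXG Channel {i}" for i in range(recording.n_channels))
            + "\n"
        )
        for i in range(recording.n_samples):
            vals = ", ".join(f"{v:.6g}" for v in recording.data[:, i])
            fh.write(f"{i}, {vals}\n")
    return path


@dataclass(frozen=True)
class ManifestEntry:
    participant_id: str
    session_label: str
    task_n: int
    trial_index: int
    recording_path: str
    behavior_path: str


@dataclass
class StudyManifest:
    """Index of a study written to disk: one entry per recording."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [
            (e.participant_id, e.session_label, e.task_n, e.trial_index)
            for e in self.entries
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (participant, session, task, trial) entries")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps([asdict(e) for e in self.entries], indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "StudyManifest":
        entries = [ManifestEntry(**e) for e in json.loads(Path(path).read_text())]
        root = Path(path).parent
        for e in entries:
            for p in (e.recording_path, e.behavior_path):
                if not (root / p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
        return cls(entries)


def write_study(study, out_dir: str | Path) -> Path:
    """Serialize a :class:`~nbackeeg.synthetic.SyntheticStudy` to a
    directory of TXT recordings + CSV behavior tables + JSON manifest.
    Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in study.recordings:
        stem = f"{rec.participant_id}_{rec.task_n}back_{rec.session_label}_t{rec.trial_index}"
        rec_path = f"{stem}.txt"
        beh_path = f"{stem}_behavior.csv"
        write_openbci_txt(rec, out_dir / rec_path)
        study.behaviors[rec.key].to_csv(out_dir / beh_path, index=False)
        entries.append(
            ManifestEntry(
                participant_id=rec.participant_id,
                session_label=rec.session_label,
                task_n=rec.task_n,
                trial_index=rec.trial_index,
                recording_path=rec_path,
                behavior_path=beh_path,
            )
        )
    return StudyManifest(entries).save(out_dir / "manifest.json")


def load_study(manifest_path: str | Path):
    """Load a study directory back into recordings + behavior tables."""
    from .synthetic import StudySpec, SyntheticStudy  # avoid import cycle

    manifest_path = Path(manifest_path)
    manifest = StudyManifest.load(manifest_path)
    root = manifest_path.parent
    recordings = []
    behaviors = {}
    for e in manifest.entries:
        rec = read_openbci_txt(
            root / e.recording_path,
            participant_id=e.participant_id,
            session_label=e.session_label,
            task_n=e.task_n,
            trial_index=e.trial_index,
        )
        recordings.append(rec)
        behaviors[rec.key] = pd.read_csv(root / e.behavior_path)
    participants = {e.participant_id for e in manifest.entries}
    trials = max(e.trial_index for e in manifest.entries)
    duration = max(r.duration_s for r in recordings)
    study = StudySpec(
        n_participants=len(participants),
        sessions_per_condition=trials,
        duration_s=max(duration, 15.0),
        sample_rate_hz=recordings[0].sample_rate_hz,
    )
    return SyntheticStudy(recordings=recordings, behaviors=behaviors, study=study)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged five-participant behavioral score table (40 scores:
    5 participants x 2 tasks x 2 sessions x 2 trials), with the printed
    high/low annotations and synthetic tie-breaking response times."""
    return table1_frame()


@dataclass
class RunConfig:
    """Flat run configuration with the published protocol as defaults.

    Every value can be overridden from YAML; see ``from_yaml``.
    """

    # preprocessing
    filter_low_hz: float = 2.0
    filter_high_hz: float = 50.0
    filter_order: int = 4
    ica_n_components: int = 8
    ica_corr_threshold: float = 0.8
    ica_z_threshold: float = 4.0
    ica_pad_s: float = 0.2
    ica_seed: int = 0
    # windowing
    crop_start_s: float = 3.0
    crop_end_s: float = 15.0
    window_s: float = 1.0
    step_s: float = 0.1
    epoch_start_s: float = 5.0
    epoch_end_s: float = 15.0
    # CNN
    conv_filters: int = 128
    conv_kernel: int = 1
    dense_units: int = 32
    epochs: int = 1000
    batch_size: int = 128
    learning_rate: float = 1e-3
    train_fraction: float = 0.7
    validation_fraction: float = 0.3
    n_repeats: int = 10
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
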