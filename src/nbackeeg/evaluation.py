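"""Model evaluation: Eq-style accuracy from confusion counts, repeated
pooled 70:30 splits, and leave-one-participant-out cross-validation.

The pooled protocol splits at the *window* level: overlapping windows
from one recording can land in both train and test, which makes pooled
accuracies optimistic - deliberately so, since this mirrors the
published protocol.  LOOCV is the honest subject-level generalization
test: the held-out participant's windows never touch training, which is
asserted by id-disjointness inside the fold loop.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import highlow_table, score_session, summarize_rates
from .classifier import ChannelwiseCNN, CNNConfig, build_model
from .core import BAND_NAMES, CHANNELS, EEGRecording
from .exact_stats import exact_signed_rank
from .features import (
    LabeledExample,
    build_dataset,
    epoch_relative_power,
    examples_to_frame,
    stack_examples,
    window_starts,
)
from .io_formats import RunConfig
from .preprocess import CleanedRecording, preprocess_chain

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "LoocvResult",
    "accuracy",
    "confusion_counts",
    "pooled_eval",
    "loocv_eval",
    "run_pipeline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; "positive" is class 1."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of zero counts")
    return (counts.tp + counts.tn) / counts.total


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _sem(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class EvalResult:
    """Repeated pooled-split evaluation summary."""

    train_accuracies: list[float]
    test_accuracies: list[float]
    train_mean: float
    train_sem: float
    test_mean: float
    test_sem: float
    confusion: ConfusionCounts
    n_examples: int
    n_windows_per_recording: int
    config: CNNConfig
    seeds: list[int]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["config"] = asdict(self.config)
        return d


@dataclass
class LoocvResult:
    """Leave-one-participant-out summary: one entry per participant."""

    per_participant: dict[str, tuple[float, float]]  # pid -> (mean, sem)
    grand_mean: float
    grand_sem: float
    config: CNNConfig
    seeds: list[int]

    def to_dict(self) -> dict:
        return {
            "per_participant": {
                k: {"mean": m, "sem": s} for k, (m, s) in self.per_participant.items()
            },
            "grand_mean": self.grand_mean,
            "grand_sem": self.grand_sem,
            "config": asdict(self.config),
            "seeds": self.seeds,
        }


def _train_once(
    X: np.ndarray, y: np.ndarray, cnn_config: CNNConfig, seed: int
) -> ChannelwiseCNN:
    model = build_model(
        CNNConfig(**{**asdict(cnn_config), "seed": int(seed)})
    )
    model.fit(X, y)
    return model


def pooled_eval(
    examples: Sequence[LabeledExample],
    cnn_config: CNNConfig,
    n_repeats: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> EvalResult:
    """Repeat a random window-level 70:30 split ``n_repeats`` times,
    train a fresh model per repeat, and report mean +/- SEM accuracy."""
    X, y, _ = stack_examples(examples)
    if np.unique(y).size < 2:
        raise ValueError("examples must contain both classes")
    X = X.transpose(0, 2, 1)  # (n, positions, channels)
    n = len(examples)
    if n < cnn_config.batch_size:
        import warnings

        warnings.warn("fewer examples than batch size; batches are clipped")
    train_accs, test_accs, seeds = [], [], []
    agg = np.zeros(4, dtype=int)
    for r in range(n_repeats):
        rep_seed = int(seed) + r
        seeds.append(rep_seed)
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        tr, te = perm[:n_train], perm[n_train:]
        model = _train_once(X[tr], y[tr], cnn_config, rep_seed)
        train_accs.append(float((model.predict(X[tr]) == y[tr]).mean()))
        pred = model.predict(X[te])
        cc = confusion_counts(y[te], pred)
        agg += np.array([cc.tp, cc.tn, cc.fp, cc.fn])
        test_accs.append(accuracy(cc))
    return EvalResult(
        train_accuracies=train_accs,
        test_accuracies=test_accs,
        train_mean=float(np.mean(train_accs)),
        train_sem=_sem(train_accs),
        test_mean=float(np.mean(test_accs)),
        test_sem=_sem(test_accs),
        confusion=ConfusionCounts(*agg.tolist()),
        n_examples=n,
        n_windows_per_recording=len(window_starts()),
        config=cnn_config,
        seeds=seeds,
    )


def loocv_eval(
    examples: Sequence[LabeledExample],
    cnn_config: CNNConfig,
    seed: int = 0,
    n_repeats: int = 3,
) -> LoocvResult:
    """Leave-one-participant-out: train on all other participants, test
    on the held-out one; repeat training ``n_repeats`` times per fold
    with different seeds and summarize each fold as mean +/- SEM."""
    X, y, pid = stack_examples(examples)
    X = X.transpose(0, 2, 1)
    participants = sorted(set(pid))
    if len(participants) < 2:
        raise ValueError("LOOCV needs at least 2 participants")
    per: dict[str, tuple[float, float]] = {}
    seeds: list[int] = []
    for i, holdout in enumerate(participants):
        test_mask = pid == holdout
        train_mask = ~test_mask
        assert not np.any(test_mask & train_mask)
        assert holdout not in set(pid[train_mask])
        if np.unique(y[train_mask]).size < 2:
            raise ValueError(
                f"training residue for held-out {holdout} has a single class"
            )
        accs = []
        for r in range(n_repeats):
            fold_seed = int(seed) + 1000 * (i + 1) + r
            seeds.append(fold_seed)
            model = _train_once(X[train_mask], y[train_mask], cnn_config, fold_seed)
            accs.append(float((model.predict(X[test_mask]) == y[test_mask]).mean()))
        per[holdout] = (float(np.mean(accs)), _sem(accs))
    fold_means = [m for m, _ in per.values()]
    return LoocvResult(
        per_participant=per,
        grand_mean=float(np.mean(fold_means)),
        grand_sem=_sem(fold_means),
        config=cnn_config,
        seeds=seeds,
    )


# -- full pipeline -------------------------------------------------------


def _score_labeler(study, task_n: int):
    """Map recordings to high/low labels via the behavioral selection rule."""
    from .behavior import select_high_low

    sessions: dict[str, list] = {}
    for rec in study.recordings_for(task_n):
        beh = study.behaviors[rec.key]
        sessions.setdefault(rec.participant_id, []).append(
            score_session(
                beh,
                participant_id=rec.participant_id,
                task_n=task_n,
                session_label=rec.session_label,
                trial_index=rec.trial_index,
            )
        )
    chosen: dict[tuple, int] = {}
    for pidn, scores in sessions.items():
        a = select_high_low(scores)
        chosen[(pidn, *a.high)] = 1
        chosen[(pidn, *a.low)] = 0

    def label_fn(rec: EEGRecording):
        return chosen.get((rec.participant_id, rec.session_label, rec.trial_index))

    return label_fn


def run_pipeline(
    study,
    config: RunConfig | None = None,
    out_dir: str | Path = "results",
    *,
    tasks: Sequence[int] | None = None,
    label_modes: Sequence[str] = ("ampm", "score"),
    representations: Sequence[str] = ("relative_power", "raw_waveform"),
    include_loocv: bool = True,
    loocv_repeats: int = 3,
) -> dict:
    """Preprocess -> featurize -> train -> evaluate an entire study and
    write a results bundle (JSON/CSV) with a reproducibility record.

    ``study`` is a :class:`~nbackeeg.synthetic.SyntheticStudy` (or the
    result of :func:`~nbackeeg.io_formats.load_study`).  Any stage
    failure aborts with a diagnostic naming the stage.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if tasks is None:
        tasks = sorted({r.task_n for r in study.recordings})
    bundle: dict = {"tasks": {}}

    cnn_config = CNNConfig(
        conv_filters=config.conv_filters,
        conv_kernel=config.conv_kernel,
        dense_units=config.dense_units,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        validation_fraction=config.validation_fraction,
        seed=config.seed,
    )

    for task in tasks:
        recs = study.recordings_for(task)
        if not recs:
            continue
        task_out: dict = {}

        # --- preprocessing ---
        try:
            cleaned = [
                preprocess_chain(
                    r,
                    low_hz=config.filter_low_hz,
                    high_hz=config.filter_high_hz,
                    order=config.filter_order,
                    ica_components=config.ica_n_components,
                    seed=config.ica_seed,
                    corr_threshold=config.ica_corr_threshold,
                    z_threshold=config.ica_z_threshold,
                    pad_s=config.ica_pad_s,
                )
                for r in recs
            ]
        except Exception as exc:
            raise RuntimeError(f"preprocess stage failed for task {task}: {exc}") from exc
        reports = {
            "_".join(map(str, c.recording.key)): c.report.to_dict() for c in cleaned
        }
        (out_dir / f"cleaning_{task}back.json").write_text(json.dumps(reports, indent=2))

        # --- epoch relative power table ---
        try:
            ep_rows = []
            for c in cleaned:
                rp = epoch_relative_power(
                    c.recording, (config.epoch_start_s, config.epoch_end_s)
                )
                for ci, ch in enumerate(CHANNELS):
                    row = {
                        "participant": c.recording.participant_id,
                        "session": c.recording.session_label,
                        "trial": c.recording.trial_index,
                        "channel": ch,
                    }
                    row.update({b: rp[ci, bi] for bi, b in enumerate(BAND_NAMES)})
                    ep_rows.append(row)
            pd.DataFrame(ep_rows).to_csv(
                out_dir / f"epoch_relative_power_{task}back.csv", index=False
            )
        except Exception as exc:
            raise RuntimeError(f"features stage failed for task {task}: {exc}") from exc

        # --- behavior ---
        beh_scores = pd.DataFrame(
            [
                {
                    "participant": r.participant_id,
                    "task_n": r.task_n,
                    "session": r.session_label,
                    "trial": r.trial_index,
                    "correct_rate_pct": score_session(study.behaviors[r.key]).correct_rate_pct,
                    "mean_rt_ms": score_session(study.behaviors[r.key]).mean_rt_ms,
                }
                for r in recs
            ]
        )
        summary = summarize_rates(beh_scores, by=("session",))
        am = beh_scores[beh_scores.session == "am"].sort_values(["participant", "trial"])
        pm = beh_scores[beh_scores.session == "pm"].sort_values(["participant", "trial"])
        stats = {}
        if len(am) == len(pm) and len(am) >= 2:
            res = exact_signed_rank(
                am["correct_rate_pct"].to_numpy(), pm["correct_rate_pct"].to_numpy()
            )
            stats = {"am_vs_pm_p": res.p_two_sided, "statistic": res.statistic}
        task_out["behavior"] = {
            "summary": summary.to_dict(orient="records"),
            "signed_rank": stats,
        }

        # --- classification ---
        for mode in label_modes:
            label_fn = None if mode == "ampm" else _score_labeler(study, task)
            for representation in representations:
                try:
                    examples = build_dataset(
                        cleaned,
                        representation=representation,
                        crop=(config.crop_start_s, config.crop_end_s),
                        step=config.step_s,
                        window_s=config.window_s,
                        label_fn=label_fn,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"features stage failed for task {task}: {exc}"
                    ) from exc
                key = f"{mode}_{representation}"
                try:
                    pooled = pooled_eval(
                        examples,
                        cnn_config,
                        n_repeats=config.n_repeats,
                        train_fraction=config.train_fraction,
                        seed=config.seed,
                    )
                    entry = {"pooled": pooled.to_dict()}
                    if include_loocv:
                        loocv = loocv_eval(
                            examples, cnn_config, seed=config.seed, n_repeats=loocv_repeats
                        )
                        entry["loocv"] = loocv.to_dict()
                except Exception as exc:
                    raise RuntimeError(
                        f"classifier/evaluation stage failed for task {task}, "
                        f"{key}: {exc}"
                    ) from exc
                entry["n_examples"] = len(examples)
                entry["n_windows_per_recording"] = len(
                    window_starts(
                        (config.crop_start_s, config.crop_end_s),
                        config.step_s,
                        config.window_s,
                    )
                )
                task_out[key] = entry
        bundle["tasks"][str(task)] = task_out

    bundle["reproducibility"] = {
        "config": asdict(config),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (out_dir / "results.json").write_text(json.dumps(bundle, indent=2, default=float))
    return bundle
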