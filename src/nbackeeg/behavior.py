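"""Behavioral scoring for the N-back task.

Each session is 20 trials; performance is the correct-answer rate (%).
Per participant and task, the sessions with the highest and lowest
rates define the high/low classes for score classification; rate ties
are broken by mean response time (shortest -> high, longest -> low),
and a residual exact tie falls back to session order, flagged.

Group summaries are mean +/- SEM over the individual trial-level scores
(10 per task-and-time group in the five-participant design); SEM uses
the n-1 sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionScore",
    "HighLowAssignment",
    "score_session",
    "select_high_low",
    "summarize_rates",
    "highlow_table",
]


@dataclass(frozen=True)
class SessionScore:
    participant_id: str
    task_n: int
    session_label: str
    trial_index: int
    n_questions: int
    n_correct: int
    mean_rt_ms: float

    @property
    def correct_rate_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_questions


@dataclass(frozen=True)
class HighLowAssignment:
    participant_id: str
    task_n: int
    high: tuple[str, int]  # (session_label, trial_index)
    low: tuple[str, int]
    tiebreak_used: bool


def score_session(
    trials: pd.DataFrame,
    *,
    participant_id: str = "P1",
    task_n: int = 2,
    session_label: str = "",
    trial_index: int = 1,
) -> SessionScore:
    """Score one 20-trial table (columns ``correct``, ``rt_ms``,
    optionally ``response``).  Missing responses count as incorrect."""
    trials = trials.copy()
    if "response" in trials.columns:
        missing = trials["response"].isna()
        if missing.any():
            trials.loc[missing, "correct"] = 0
    correct = trials["correct"].astype(bool)
    answered = (
        ~trials["response"].isna() if "response" in trials.columns
        else pd.Series(True, index=trials.index)
    )
    rts = trials.loc[answered, "rt_ms"]
    return SessionScore(
        participant_id=participant_id,
        task_n=task_n,
        session_label=session_label,
        trial_index=trial_index,
        n_questions=len(trials),
        n_correct=int(correct.sum()),
        mean_rt_ms=float(rts.mean()) if len(rts) else float("nan"),
    )


def select_high_low(scores: Sequence[SessionScore]) -> HighLowAssignment:
    """Pick the high- and low-scoring session among one participant's
    sessions of one task.  Ties on rate break by mean response time
    (shortest wins high, longest wins low); any remaining exact tie
    falls back to earlier session order and sets ``tiebreak_used``."""
    if len(scores) < 2:
        raise ValueError("need at least 2 sessions to pick high/low")
    pids = {s.participant_id for s in scores}
    tasks = {s.task_n for s in scores}
    if len(pids) != 1 or len(tasks) != 1:
        raise ValueError("scores must come from one participant and one task")

    order = list(scores)  # session order as given

    def high_key(i: int):
        s = order[i]
        return (-s.correct_rate_pct, s.mean_rt_ms, i)

    def low_key(i: int):
        s = order[i]
        return (s.correct_rate_pct, -s.mean_rt_ms, i)

    hi = min(range(len(order)), key=high_key)
    lo = min(range(len(order)), key=low_key)
    if hi == lo:  # every session identical: order decides both slots
        lo = min((i for i in range(len(order)) if i != hi), key=low_key)

    rates = [s.correct_rate_pct for s in order]
    # rates alone did not decide: RT (or, failing that, order) was consulted
    tiebreak = rates.count(max(rates)) > 1 or rates.count(min(rates)) > 1
    s_hi, s_lo = order[hi], order[lo]
    return HighLowAssignment(
        participant_id=s_hi.participant_id,
        task_n=s_hi.task_n,
        high=(s_hi.session_label, s_hi.trial_index),
        low=(s_lo.session_label, s_lo.trial_index),
        tiebreak_used=tiebreak,
    )


def summarize_rates(
    scores: pd.DataFrame, by: Sequence[str] = ("task_n", "session")
) -> pd.DataFrame:
    """Mean +/- SEM of ``correct_rate_pct`` per group of trial-level scores."""
    if scores.empty:
        raise ValueError("empty score table")

    def agg(g: pd.Series) -> pd.Series:
        if len(g) < 2:
            raise ValueError("need >= 2 scores per group for a SEM")
        return pd.Series(
            {
                "mean_pct": g.mean(),
                "sem_pct": g.std(ddof=1) / np.sqrt(len(g)),
                "n": len(g),
            }
        )

    out = (
        scores.groupby(list(by))["correct_rate_pct"].apply(agg).unstack().reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def _fixture_scores(frame: pd.DataFrame, participant: int, task_n: int) -> list[SessionScore]:
    rows = frame[(frame["participant"] == participant) & (frame["task_n"] == task_n)]
    # fixed session order: am1, am2, pm1, pm2
    rows = rows.sort_values(["session", "trial"])
    return [
        SessionScore(
            participant_id=f"P{participant}",
            task_n=task_n,
            session_label=r.session,
            trial_index=int(r.trial),
            n_questions=20,
            n_correct=int(round(r.correct_rate_pct / 5.0)),
            mean_rt_ms=float(r.mean_rt_ms),
        )
        for r in rows.itertuples()
    ]


def highlow_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`select_high_low` to every participant x task cell of a
    fixture-shaped score table; returns one row per cell."""
    rows = []
    for task in sorted(frame["task_n"].unique()):
        for p in sorted(frame["participant"].unique()):
            a = select_high_low(_fixture_scores(frame, p, task))
            rows.append(
                {
                    "participant": p,
                    "task_n": task,
                    "high_session": a.high[0],
                    "high_trial": a.high[1],
                    "low_session": a.low[0],
                    "low_trial": a.low[1],
                    "tiebreak_used": a.tiebreak_used,
                }
            )
    return pd.DataFrame(rows)
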