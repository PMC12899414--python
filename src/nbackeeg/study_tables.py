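"""Packaged reference tables from a five-participant N-back pilot study.

Two fixtures live here:

* ``TABLE1_SCORES`` - correct-answer rates (%) for five participants, each
  performing the 2- and 3-back task twice in the morning (8-9 a.m.) and
  twice in the afternoon (3-4 p.m.).  The published table also marks, per
  participant and task, the high- and low-scoring session.  Mean response
  times were not published; the ``rt_ms`` values here are SYNTHETIC,
  constructed only to be consistent with the printed high/low markings
  (rate ties are broken by response time: shortest -> high, longest -> low).

* ``RELATIVE_POWER_MEANS`` - group-mean six-band relative powers (%) per
  channel, task and time of day.  These parameterize the synthetic EEG
  generator so simulated studies carry the observed effect structure
  (e.g. T6 theta 24.1% a.m. vs 35.4% p.m. in the 2-back task).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BAND_NAMES, CHANNELS

# (participant, task_n, session, trial) -> (correct %, synthetic mean RT ms)
# high/low markings are encoded separately below.
TABLE1_SCORES: tuple[tuple[int, int, str, int, int, int], ...] = (
    # participant, task, session, trial, rate %, rt_ms (synthetic)
    (1, 2, "am", 1, 75, 720), (1, 2, "am", 2, 70, 745),
    (1, 2, "pm", 1, 80, 700), (1, 2, "pm", 2, 90, 660),
    (2, 2, "am", 1, 90, 690), (2, 2, "am", 2, 90, 705),
    (2, 2, "pm", 1, 85, 715), (2, 2, "pm", 2, 90, 655),
    (3, 2, "am", 1, 85, 700), (3, 2, "am", 2, 65, 760),
    (3, 2, "pm", 1, 95, 640), (3, 2, "pm", 2, 85, 690),
    (4, 2, "am", 1, 80, 710), (4, 2, "am", 2, 70, 750),
    (4, 2, "pm", 1, 80, 705), (4, 2, "pm", 2, 95, 645),
    (5, 2, "am", 1, 90, 675), (5, 2, "am", 2, 85, 700),
    (5, 2, "pm", 1, 90, 680), (5, 2, "pm", 2, 95, 650),
    (1, 3, "am", 1, 65, 880), (1, 3, "am", 2, 80, 800),
    (1, 3, "pm", 1, 60, 910), (1, 3, "pm", 2, 70, 860),
    (2, 3, "am", 1, 75, 850), (2, 3, "am", 2, 85, 815),
    (2, 3, "pm", 1, 85, 820), (2, 3, "pm", 2, 90, 780),
    (3, 3, "am", 1, 50, 950), (3, 3, "am", 2, 80, 810),
    (3, 3, "pm", 1, 75, 840), (3, 3, "pm", 2, 65, 890),
    (4, 3, "am", 1, 65, 905), (4, 3, "am", 2, 65, 870),
    (4, 3, "pm", 1, 90, 790), (4, 3, "pm", 2, 85, 805),
    (5, 3, "am", 1, 50, 960), (5, 3, "am", 2, 65, 900),
    (5, 3, "pm", 1, 55, 930), (5, 3, "pm", 2, 65, 875),
)

# Printed high (bold) sessions: (participant, task) -> (session, trial)
TABLE1_HIGH: dict[tuple[int, int], tuple[str, int]] = {
    (1, 2): ("pm", 2), (2, 2): ("pm", 2), (3, 2): ("pm", 1),
    (4, 2): ("pm", 2), (5, 2): ("pm", 2),
    (1, 3): ("am", 2), (2, 3): ("pm", 2), (3, 3): ("am", 2),
    (4, 3): ("pm", 1), (5, 3): ("pm", 2),
}

# Low (underlined) sessions.  All are the unique rate minimum except
# (4, 3), where a.m. 1st/2nd tie at 65% and the synthetic RTs resolve
# the tie toward a.m. 1st.
TABLE1_LOW: dict[tuple[int, int], tuple[str, int]] = {
    (1, 2): ("am", 2), (2, 2): ("pm", 1), (3, 2): ("am", 2),
    (4, 2): ("am", 2), (5, 2): ("am", 2),
    (1, 3): ("pm", 1), (2, 3): ("am", 1), (3, 3): ("am", 1),
    (4, 3): ("am", 1), (5, 3): ("am", 1),
}

# Group-mean relative powers (%), rows in CHANNELS order, columns in
# BAND_NAMES order (delta, theta, alpha, beta1, beta2, gamma).
RELATIVE_POWER_MEANS: dict[tuple[int, str], tuple[tuple[float, ...], ...]] = {
    (2, "am"): (
        (1.4, 38.0, 26.8, 16.8, 10.9, 6.1),
        (1.3, 35.5, 27.1, 15.0, 13.3, 7.8),
        (1.2, 34.4, 30.4, 16.3, 11.0, 6.7),
        (1.4, 39.4, 30.3, 15.2, 8.4, 5.3),
        (1.5, 37.3, 27.1, 17.8, 10.4, 5.9),
        (1.2, 24.1, 29.0, 20.4, 16.1, 9.1),
        (0.9, 24.6, 28.2, 21.3, 15.3, 9.7),
        (1.0, 30.6, 26.0, 19.9, 14.4, 8.1),
    ),
    (2, "pm"): (
        (1.2, 41.0, 27.0, 14.8, 10.3, 5.6),
        (1.1, 41.2, 24.7, 13.8, 12.0, 7.2),
        (1.0, 41.7, 27.3, 15.5, 9.2, 5.3),
        (1.1, 37.2, 29.9, 15.0, 10.6, 6.2),
        (0.8, 34.4, 27.5, 17.3, 12.3, 7.7),
        (0.6, 35.4, 29.2, 18.2, 10.6, 5.9),
        (0.8, 33.6, 24.5, 18.2, 14.1, 8.8),
        (1.0, 34.9, 26.3, 17.5, 12.8, 7.6),
    ),
    (3, "am"): (
        (2.3, 44.1, 22.9, 14.5, 10.2, 6.0),
        (2.3, 41.7, 22.4, 13.6, 12.1, 7.9),
        (1.9, 42.2, 24.8, 16.2, 9.6, 5.2),
        (2.0, 42.7, 25.6, 15.5, 9.0, 5.2),
        (2.0, 39.0, 23.5, 16.9, 12.0, 6.5),
        (1.1, 30.2, 24.6, 20.0, 16.1, 8.0),
        (1.1, 29.7, 25.6, 19.8, 14.6, 9.2),
        (1.4, 36.7, 23.1, 18.8, 12.9, 7.1),
    ),
    (3, "pm"): (
        (1.7, 40.8, 22.6, 15.2, 13.1, 6.6),
        (1.3, 39.0, 23.1, 16.7, 12.2, 7.7),
        (1.2, 42.1, 25.5, 15.5, 9.6, 6.1),
        (1.1, 39.2, 28.1, 15.8, 10.3, 5.5),
        (0.9, 35.3, 24.3, 17.7, 13.3, 8.5),
        (0.8, 35.5, 26.8, 19.0, 11.7, 6.1),
        (0.8, 28.2, 24.5, 21.7, 15.3, 9.5),
        (1.0, 37.2, 25.5, 16.6, 12.1, 7.5),
    ),
}


def table1_frame() -> pd.DataFrame:
    """Behavioral fixture as a tidy DataFrame.

    Columns: participant, task_n, session, trial, correct_rate_pct,
    mean_rt_ms (synthetic), high, low (the printed markings).
    """
    rows = []
    for p, task, session, trial, rate, rt in TABLE1_SCORES:
        rows.append(
            {
                "participant": p,
                "task_n": task,
                "session": session,
                "trial": trial,
                "correct_rate_pct": float(rate),
                "mean_rt_ms": float(rt),
                "high": TABLE1_HIGH[(p, task)] == (session, trial),
                "low": TABLE1_LOW[(p, task)] == (session, trial),
            }
        )
    return pd.DataFrame(rows)


def relative_power_matrix(task_n: int, session: str) -> np.ndarray:
    """Group-mean relative powers as an (8 channels, 6 bands) fraction matrix.

    Rows are renormalized to sum exactly to 1 (the printed percentages
    round to one decimal and sum to ~100).
    """
    m = np.asarray(RELATIVE_POWER_MEANS[(task_n, session)], dtype=float)
    assert m.shape == (len(CHANNELS), len(BAND_NAMES))
    return m / m.sum(axis=1, keepdims=True)
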