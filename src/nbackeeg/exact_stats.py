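"""Exact Wilcoxon signed-rank and rank-sum tests by full enumeration.

With five participants the asymptotic chi-square/normal null is a poor
approximation, so p-values here come from the complete permutation
distribution, conditional on the observed (midrank-tied) ranks:

* signed-rank: all 2^n sign assignments of the |difference| ranks;
* rank-sum: all C(n+m, n) assignments of the pooled ranks to groups.

Two-sided p-values sum both tails of the exact distribution at least as
extreme as the observed statistic (not one tail doubled), which stays
correct when ties make the distribution asymmetric.  The null
distributions are accumulated with a generating-function recursion over
doubled (integer) midranks - algebraically identical to enumerating
every assignment, but O(n * max_sum) instead of exponential.

Zero differences are dropped by default (Wilcoxon's convention); the
Pratt variant (rank zeros, then discard their ranks) is available via
``zero_policy="pratt"``.  No multiple-comparison correction is applied
anywhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ExactTestResult", "exact_signed_rank", "exact_rank_sum", "signed_rank_table"]

_MAX_SIGNED_N = 25
_MAX_RANKSUM_N = 22


@dataclass(frozen=True)
class ExactTestResult:
    statistic: float
    p_two_sided: float
    n_used: int
    ties_present: bool
    zero_policy: str | None
    method: str

    def __post_init__(self) -> None:
        if not 0.0 < self.p_two_sided <= 1.0 + 1e-12:
            raise ValueError("p-value out of range")


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """counts[s] = number of sign assignments with doubled rank sum s."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: counts.size - r]
        counts = new
    return counts


def exact_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    zero_policy: str = "drop",
) -> ExactTestResult:
    """Exact Wilcoxon signed-rank test on paired data (or on ``x`` as
    precomputed differences when ``y`` is None).

    The statistic is W+ (sum of midranks of positive differences); the
    two-sided p is P(min(W+, W-) <= observed min) over all 2^n sign
    assignments.  All-zero differences give p = 1 with a warning; n > 25
    is refused (use an asymptotic test at that size).
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    if zero_policy not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return ExactTestResult(0.0, 1.0, 0, False, zero_policy, "signed_rank")

    if zero_policy == "drop":
        dd = d[nonzero]
        ranks = rankdata(np.abs(dd))
    else:  # pratt: rank zeros too, then discard their ranks
        ranks_all = rankdata(np.abs(d))
        dd = d[nonzero]
        ranks = ranks_all[nonzero]
    n = dd.size
    if n > _MAX_SIGNED_N:
        raise ValueError(
            f"n = {n} > {_MAX_SIGNED_N}: exact enumeration refused; "
            "use an asymptotic signed-rank test"
        )
    ties = len(np.unique(np.abs(dd))) < n or (zero_policy == "pratt" and (~nonzero).any())

    ranks2 = np.round(2 * ranks).astype(int)
    total2 = int(ranks2.sum())
    w2 = int(np.round(ranks2[dd > 0].sum()))
    m2_obs = min(w2, total2 - w2)

    counts = _signed_rank_distribution(ranks2)
    sums = np.arange(counts.size)
    extreme = np.minimum(sums, total2 - sums) <= m2_obs
    p = float(counts[extreme].sum() / 2.0**n)
    return ExactTestResult(w2 / 2.0, min(p, 1.0), n, ties, zero_policy, "signed_rank")


def _rank_sum_distribution(ranks2: np.ndarray, n: int) -> np.ndarray:
    """dist[s] = number of n-subsets of the doubled ranks with sum s."""
    total = int(ranks2.sum())
    dp = np.zeros((n + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(min(n, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n]


def exact_rank_sum(x: Sequence[float], y: Sequence[float]) -> ExactTestResult:
    """Exact Wilcoxon rank-sum test for two independent samples.

    The statistic is the rank sum of ``x`` over the pooled midranks; the
    two-sided p sums both tails at least as far from the null mean as
    the observed statistic, over all C(n+m, n) group assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n, m = x.size, y.size
    if n + m > _MAX_RANKSUM_N:
        raise ValueError(
            f"n + m = {n + m} > {_MAX_RANKSUM_N}: exact enumeration refused"
        )
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    ties = len(np.unique(pooled)) < pooled.size
    ranks2 = np.round(2 * ranks).astype(int)
    w2 = int(ranks2[:n].sum())
    mean2 = n * ranks2.sum() / (n + m)

    dist = _rank_sum_distribution(ranks2, n)
    sums = np.arange(dist.size)
    extreme = np.abs(sums - mean2) >= abs(w2 - mean2) - 1e-9
    p = float(dist[extreme].sum() / comb(n + m, n))
    return ExactTestResult(w2 / 2.0, min(p, 1.0), n + m, ties, None, "rank_sum")


def signed_rank_table(
    a: pd.DataFrame, b: pd.DataFrame, zero_policy: str = "drop"
) -> pd.DataFrame:
    """Column-wise paired exact tests between two aligned tables.

    Rows are paired observations (e.g. sessions), columns are measures
    (e.g. channel-band relative powers).  Returns one row per column
    with group means, SEMs and the exact two-sided p - the layout used
    for condition-comparison tables.
    """
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        raise ValueError("tables must be aligned (same columns and length)")
    rows = []
    for col in a.columns:
        res = exact_signed_rank(a[col].to_numpy(), b[col].to_numpy(), zero_policy)
        rows.append(
            {
                "measure": col,
                "mean_a": a[col].mean(),
                "sem_a": a[col].std(ddof=1) / np.sqrt(len(a)),
                "mean_b": b[col].mean(),
                "sem_b": b[col].std(ddof=1) / np.sqrt(len(b)),
                "statistic": res.statistic,
                "p_two_sided": res.p_two_sided,
                "n_used": res.n_used,
            }
        )
    return pd.DataFrame(rows)
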