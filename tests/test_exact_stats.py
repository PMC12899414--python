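"""Exact Wilcoxon tests against literal brute-force enumeration.

The oracles here enumerate every sign assignment (signed-rank) or every
group assignment (rank-sum) directly with itertools, independently of
the package's generating-function implementation.
"""

import itertools
import warnings
from math import comb

import numpy as np
import pytest
from scipy.stats import rankdata

from nbackeeg.exact_stats import exact_rank_sum, exact_signed_rank, signed_rank_table


def brute_signed_rank_p(d, zero_policy="drop"):
    """Literal 2^n enumeration of sign assignments, midranks for ties."""
    d = np.asarray(d, dtype=float)
    if zero_policy == "drop":
        dd = d[d != 0]
        ranks = rankdata(np.abs(dd))
    else:
        ranks = rankdata(np.abs(d))[d != 0]
        dd = d[d != 0]
    n = dd.size
    S = ranks.sum()
    w_obs = ranks[dd > 0].sum()
    m_obs = min(w_obs, S - w_obs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, S - w) <= m_obs + 1e-9:
            count += 1
    return count / 2**n


def brute_rank_sum_p(x, y):
    """Literal C(n+m, n) enumeration of group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n].sum()
    mean = n * ranks.sum() / (n + m)
    count = 0
    for idx in itertools.combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        if abs(w - mean) >= abs(w_obs - mean) - 1e-9:
            count += 1
    return count / comb(n + m, n)


class TestSignedRank:
    def test_all_positive_no_ties(self):
        """n=5, every difference positive: W+ = 15, p = 2/32."""
        res = exact_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.statistic == 15.0
        assert res.p_two_sided == pytest.approx(2 / 32)
        assert res.n_used == 5 and not res.ties_present

    def test_symmetric_two_pairs(self):
        res = exact_signed_rank([1.0, -1.0])
        assert res.p_two_sided == 1.0

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            res = exact_signed_rank([0.0, 0.0, 0.0])
        assert res.p_two_sided == 1.0 and res.n_used == 0

    def test_refuses_large_n(self):
        with pytest.raises(ValueError, match="asymptotic"):
            exact_signed_rank(np.arange(1.0, 28.0))

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        assert (
            exact_signed_rank(x, y).p_two_sided
            == exact_signed_rank(y, x).p_two_sided
        )

    @pytest.mark.parametrize("zero_policy", ["drop", "pratt"])
    def test_matches_bruteforce(self, zero_policy, rng):
        """Generating-function recursion == literal 2^n enumeration,
        with and without ties/zeros, n up to 10."""
        for _ in range(40):
            n = int(rng.integers(2, 11))
            if rng.random() < 0.5:  # tie- and zero-prone integer differences
                d = rng.integers(-3, 4, size=n).astype(float)
            else:
                d = rng.normal(size=n)
            if not np.any(d != 0):
                continue
            res = exact_signed_rank(d, zero_policy=zero_policy)
            assert res.p_two_sided == pytest.approx(
                brute_signed_rank_p(d, zero_policy), abs=1e-12
            )


class TestRankSum:
    def test_complete_separation(self):
        """n=m=3, disjoint groups: p = 2 / C(6,3) = 0.1."""
        res = exact_rank_sum([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_multisets(self):
        res = exact_rank_sum([1.0, 2.0, 2.0], [2.0, 1.0, 2.0])
        assert res.p_two_sided == 1.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        p0 = exact_rank_sum(x, y).p_two_sided
        f = lambda v: np.exp(3 * v) + 1  # strictly increasing
        assert exact_rank_sum(f(x), f(y)).p_two_sided == pytest.approx(p0)

    def test_refuses_oversized(self):
        with pytest.raises(ValueError, match="refused"):
            exact_rank_sum(np.arange(12.0), np.arange(12.0))

    def test_matches_bruteforce(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            if rng.random() < 0.5:
                x = rng.integers(0, 5, size=n).astype(float)
                y = rng.integers(0, 5, size=m).astype(float)
            else:
                x = rng.normal(size=n)
                y = rng.normal(size=m)
            res = exact_rank_sum(x, y)
            assert res.p_two_sided == pytest.approx(brute_rank_sum_p(x, y), abs=1e-12)


@pytest.mark.parametrize("with_ties", [False, True])
def test_null_type_I_error_is_controlled(with_ties, rng):
    """Exact p-values are super-uniform under the null: rejection rate at
    alpha=0.05 stays at or below 0.05 up to Monte-Carlo error."""
    n_sim = 400
    rej_sr = rej_rs = 0
    for _ in range(n_sim):
        n = int(rng.integers(5, 11))
        if with_ties:
            d = rng.integers(-2, 3, size=n).astype(float)
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
        else:
            d = rng.normal(size=n)
            x = rng.normal(size=6)
            y = rng.normal(size=6)
        if np.any(d != 0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if exact_signed_rank(d).p_two_sided <= 0.05:
                    rej_sr += 1
        if exact_rank_sum(x, y).p_two_sided <= 0.05:
            rej_rs += 1
    mc_slack = 3 * np.sqrt(0.05 * 0.95 / n_sim)  # ~0.033
    assert rej_sr / n_sim <= 0.05 + mc_slack
    assert rej_rs / n_sim <= 0.05 + mc_slack


def test_signed_rank_table_layout(rng):
    import pandas as pd

    a = pd.DataFrame(rng.normal(size=(8, 3)), columns=["u", "v", "w"])
    b = pd.DataFrame(rng.normal(size=(8, 3)), columns=["u", "v", "w"])
    out = signed_rank_table(a, b)
    assert list(out["measure"]) == ["u", "v", "w"]
    assert ((out["p_two_sided"] > 0) & (out["p_two_sided"] <= 1)).all()
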