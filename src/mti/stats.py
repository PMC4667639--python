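"""Statistical tests used across the pipeline.

The repression and usage comparisons all reduce to four classical tests:

* one-sided two-sample Kolmogorov-Smirnov (target vs non-target ECDFs),
* two-sided Wilcoxon signed-rank (paired poly(A)-usage values),
* two-sided Mann-Whitney U (usage of one gene group vs another),
* two-sided Fisher exact (gene-set overlap in feed-forward loops).

Small samples get exact null distributions (enumeration or convolution,
both handle midrank ties); large samples use the standard asymptotics.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from math import comb, exp

import numpy as np
import scipy.stats

__all__ = [
    "TestResult",
    "ecdf",
    "ks_one_sided",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "fisher_exact_2x2",
]

#: Largest per-group size for which the KS permutation null is enumerated.
KS_EXACT_MAX_N = 10
#: Largest n for which the signed-rank null is computed exactly.
WILCOXON_EXACT_MAX_N = 25
#: Largest number of label assignments enumerated for Mann-Whitney.
MW_EXACT_MAX_COMB = 20_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    n_target: int
    n_nontarget: int
    alternative: str
    method: str = ""

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_target": self.n_target,
            "n_nontarget": self.n_nontarget,
            "alternative": self.alternative,
            "method": self.method,
        }


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Step-function coordinates of the empirical CDF (sorted x, F(x))."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    return x, np.arange(1, x.size + 1) / x.size


def _dplus(target: np.ndarray, nontarget: np.ndarray) -> float:
    """sup_x [ F_target(x) - F_nontarget(x) ], both ECDFs right-continuous."""
    t = np.sort(target)
    nt = np.sort(nontarget)
    allx = np.concatenate([t, nt])
    ft = np.searchsorted(t, allx, side="right") / t.size
    fnt = np.searchsorted(nt, allx, side="right") / nt.size
    return float(np.max(ft - fnt))


def ks_one_sided(
    values_target,
    values_nontarget,
    exact_max_n: int = KS_EXACT_MAX_N,
) -> TestResult:
    """One-sided two-sample KS test: targets stochastically *smaller*.

    The statistic is ``D+ = sup_x (F_target - F_nontarget)``, large when
    target values are shifted left.  For small samples the p value is the
    exact permutation probability over all label assignments; otherwise
    the standard one-sided bound ``exp(-2 m n D^2 / (m+n))``.
    """
    t = np.asarray(values_target, dtype=float)
    nt = np.asarray(values_nontarget, dtype=float)
    if t.size == 0 or nt.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _dplus(t, nt)
    n, m = t.size, nt.size
    if min(n, m) <= exact_max_n and comb(n + m, n) <= 200_000:
        pooled = np.concatenate([t, nt])
        idx_all = np.arange(n + m)
        count = total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            dp = _dplus(pooled[mask], pooled[idx_all[~mask]])
            total += 1
            if dp >= d - 1e-12:
                count += 1
        p = count / total
        method = "exact-permutation"
    else:
        p = min(1.0, exp(-2.0 * m * n * d * d / (m + n)))
        method = "asymptotic"
    return TestResult(d, p, n, m, "target values stochastically smaller", method)


def _signed_rank_exact_p(doubled_ranks: list[int], w_plus_doubled: int) -> float:
    """Exact two-sided p for the signed-rank test, ties allowed.

    Convolves the null distribution of 2*W+ over independent sign flips of
    the doubled midranks; p = P(min(W+, W-) <= observed min).
    """
    dist: dict[int, int] = {0: 1}
    for r in doubled_ranks:
        nxt: dict[int, int] = defaultdict(int)
        for s, c in dist.items():
            nxt[s] += c
            nxt[s + r] += c
        dist = dict(nxt)
    total = 2 ** len(doubled_ranks)
    s_all = sum(doubled_ranks)
    t = min(w_plus_doubled, s_all - w_plus_doubled)
    hits = sum(c for s, c in dist.items() if s <= t or s >= s_all - t)
    return min(1.0, hits / total)


def wilcoxon_signed_rank(
    paired_a,
    paired_b,
    exact_max_n: int = WILCOXON_EXACT_MAX_N,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped first; if every difference is zero the
    comparison is degenerate and p = 1 is reported.  Exact null (with
    midrank ties) up to ``exact_max_n`` informative pairs, then the normal
    approximation with continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size == 0:
        raise ValueError("no pairs supplied")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, a.size, a.size, "two-sided",
                          "degenerate-all-zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = [int(round(2 * r)) for r in ranks]
        p = _signed_rank_exact_p(doubled, int(round(2 * w_plus)))
        method = "exact"
    else:
        res = scipy.stats.wilcoxon(
            d, zero_method="wilcox", correction=True,
            alternative="two-sided", method="approx",
        )
        p = float(res.pvalue)
        method = "normal-approx"
    return TestResult(w_plus, p, n, n, "two-sided", method)


def mann_whitney(
    group_a,
    group_b,
    exact_max_comb: int = MW_EXACT_MAX_COMB,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all label assignments for small groups (midrank
    ties handled naturally); asymptotic normal with tie correction and
    continuity correction otherwise.  Statistic is U for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    center = n * m / 2.0
    dev = abs(u_obs - center)
    if comb(n + m, n) <= exact_max_comb:
        count = total = 0
        base = n * (n + 1) / 2
        for idx in itertools.combinations(range(n + m), n):
            u = float(ranks[list(idx)].sum() - base)
            total += 1
            if abs(u - center) >= dev - 1e-9:
                count += 1
        p = count / total
        method = "exact-enumeration"
    else:
        res = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        p = float(res.pvalue)
        method = "normal-approx"
    return TestResult(u_obs, min(1.0, p), n, m, "two-sided", method)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table -> (odds_ratio, p)."""
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    odds, p = scipy.stats.fisher_exact(tab, alternative="two-sided")
    return float(odds), float(p)
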