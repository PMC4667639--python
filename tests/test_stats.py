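"""Exact small-sample behaviour of the test statistics against brute force."""

import itertools
from math import comb

import numpy as np
import pytest
import scipy.stats

from mti.stats import (
    ecdf,
    fisher_exact_2x2,
    ks_one_sided,
    mann_whitney,
    wilcoxon_signed_rank,
)


# ------------------------------------------------------------- oracles

def brute_dplus(t, nt):
    t, nt = np.asarray(t, float), np.asarray(nt, float)
    xs = np.concatenate([t, nt])
    return max(
        np.mean(t <= x) - np.mean(nt <= x) for x in xs
    )


def brute_ks_p(t, nt):
    """Exhaustive permutation p for D+ over all label assignments."""
    pooled = np.concatenate([t, nt])
    n = len(t)
    d_obs = brute_dplus(t, nt)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        total += 1
        if brute_dplus(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def brute_wilcoxon_p(a, b):
    """Exhaustive sign-assignment p: P(min(W+, W-) <= observed min)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total_rank = ranks.sum()
    t_obs = min(w_plus, total_rank - w_plus)
    hits = total = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        total += 1
        if min(w, total_rank - w) <= t_obs + 1e-9:
            hits += 1
    return hits / total


def brute_mw_p(a, b):
    """Exhaustive label-assignment p with U from pairwise comparisons."""
    def u_stat(x, y):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi in x for yi in y
        )

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    dev = abs(u_stat(a, b) - n * m / 2)
    hits = total = 0
    for idx in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, bool)
        mask[list(idx)] = True
        total += 1
        if abs(u_stat(pooled[mask], pooled[~mask]) - n * m / 2) >= dev - 1e-9:
            hits += 1
    return hits / total


def hypergeom_fisher_p(table):
    """Two-sided Fisher p as a sum of hypergeometric point probabilities."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    pmf = lambda x: (
        comb(n1, x) * comb(n2, k - x) / comb(n, k)
    )
    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, k - n2), min(k, n1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-9)
    )


# ------------------------------------------------------------- KS

class TestKS:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        res = ks_one_sided(x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0])

    def test_small_sample_exact_equals_enumeration(self, rng):
        for _ in range(20):
            t = rng.normal(size=4)
            nt = rng.normal(size=4)
            res = ks_one_sided(t, nt)
            assert res.method == "exact-permutation"
            assert res.p_value == pytest.approx(brute_ks_p(t, nt), abs=1e-12)

    def test_planted_shift_rejects_strongly(self, rng):
        nt = rng.normal(0.0, 0.2, size=200)  # log2-ratio-scale dispersion
        t = nt - 0.5
        res = ks_one_sided(t, nt)
        assert res.p_value < 1e-6

    def test_asymptotic_agrees_with_permutation_within_factor_two(self, rng):
        """At a moderate effect the closed-form bound tracks a 10,000-draw
        Monte-Carlo permutation p within a factor of two."""
        nt = rng.normal(size=100)
        t = rng.normal(size=100) - 0.22
        res = ks_one_sided(t, nt)
        pooled = np.concatenate([t, nt])
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if _dplus_fast(pooled[:100], pooled[100:]) >= res.statistic - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert 0.5 * p_perm <= res.p_value <= 2.0 * p_perm

    def test_wrong_direction_gives_large_p(self, rng):
        nt = rng.normal(size=100)
        res = ks_one_sided(nt + 0.5, nt)  # targets larger, not smaller
        assert res.p_value > 0.5


def _dplus_fast(t, nt):
    t, nt = np.sort(t), np.sort(nt)
    allx = np.concatenate([t, nt])
    return np.max(
        np.searchsorted(t, allx, side="right") / t.size
        - np.searchsorted(nt, allx, side="right") / nt.size
    )


def test_ecdf_steps():
    x, y = ecdf([3.0, 1.0, 2.0])
    assert x.tolist() == [1.0, 2.0, 3.0]
    assert y.tolist() == [pytest.approx(1 / 3), pytest.approx(2 / 3), 1.0]


# ------------------------------------------------------------- Wilcoxon

class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0
        assert res.method == "degenerate-all-zero"

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_exact_equals_sign_enumeration(self, n, rng):
        for _ in range(25):
            a = rng.normal(size=n)
            b = a + rng.choice([-0.5, 0.25, 0.5, 1.0], size=n)
            res = wilcoxon_signed_rank(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_wilcoxon_p(a, b),
                                                abs=1e-10)

    def test_tied_absolute_differences_handled(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.5, 0.5, -0.5, 0.5, 0.5, 0.5])
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(brute_wilcoxon_p(a, b), abs=1e-10)

    def test_large_sample_planted_shift(self, rng):
        a = rng.normal(size=2000)
        shift = np.zeros(2000)
        shift[:1000] = 0.2
        res = wilcoxon_signed_rank(a + shift, a)
        assert res.method == "normal-approx"
        assert res.p_value < 1e-6


# ------------------------------------------------------------- Mann-Whitney

class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # U = nm/2
        assert res.p_value == 1.0

    @pytest.mark.parametrize("sizes", [(4, 5), (3, 3), (5, 5)])
    def test_exact_equals_label_enumeration(self, sizes, rng):
        n, m = sizes
        for _ in range(25):
            a = np.round(rng.normal(size=n), 1)  # rounding induces ties
            b = np.round(rng.normal(size=m), 1)
            res = mann_whitney(a, b)
            assert res.method == "exact-enumeration"
            assert res.p_value == pytest.approx(brute_mw_p(a, b), abs=1e-10)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_large_sample_shift_detected(self, rng):
        a = rng.uniform(0.2, 0.5, size=60)
        b = rng.uniform(0.4, 0.7, size=90)
        res = mann_whitney(a, b)
        assert res.method == "normal-approx"
        assert res.p_value < 1e-6


# ------------------------------------------------------------- Fisher

class TestFisher:
    def test_matches_hypergeometric_oracle(self, rng):
        for _ in range(50):
            table = rng.integers(0, 25, size=(2, 2))
            _, p = fisher_exact_2x2(table)
            assert p == pytest.approx(hypergeom_fisher_p(table.tolist()),
                                      abs=1e-10)

    def test_spec_table(self):
        _, p = fisher_exact_2x2([[10, 10], [10, 70]])
        assert p == pytest.approx(hypergeom_fisher_p([[10, 10], [10, 70]]),
                                  abs=1e-10)

    def test_bad_table_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
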