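"""Overlap enrichment and directional concordance statistics.

The hypergeometric tail is cross-checked against a brute-force subset
enumeration oracle; the binomial concordance tail against a Bernoulli
simulation oracle; the permutation estimator against both.
"""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from concord.overlap import (
    ContingencyTable,
    background_agreement_prob,
    directional_concordance,
    hypergeometric_p,
    odds_ratio_and_jaccard,
    overlap_counts,
    permutation_overlap_p,
    compare_signatures,
)
from concord.signatures import Condition, SignatureSet
from conftest import make_table


def sig(members, directions=None, agent="A"):
    members = frozenset(members)
    if directions is None:
        directions = {m: 1 for m in members}
    return SignatureSet(Condition(agent, 24.0, "gene"), members, directions)


def enum_hyper_tail(N, kA, kB, a):
    """Exact tail by enumerating every kA-subset of an N-universe."""
    universe = range(N)
    B = set(range(kB))
    hits = total = 0
    for s in combinations(universe, kA):
        total += 1
        if len(B & set(s)) >= a:
            hits += 1
    return hits / total


class TestOverlapCounts:
    def test_printed_crossmodal_counts(self):
        U = [f"x{i}" for i in range(1235)]
        A = sig(U[:28] + U[400:444])
        B = sig(U[:28] + U[44:380], agent="B")
        t = overlap_counts(A, B, U)
        assert (t.a, t.b, t.c, t.d) == (28, 44, 336, 827)
        assert t.N == 1235
        assert t.expected_overlap == pytest.approx(72 * 364 / 1235)

    def test_empty_and_full(self):
        U = list("abcdefgh")
        B = sig("abc", agent="B")
        t = overlap_counts(sig([]), B, U)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 3, 5)
        t = overlap_counts(sig(U), sig(U, agent="B"), U)
        assert (t.a, t.b, t.c, t.d) == (8, 0, 0, 0)

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            overlap_counts(sig(["z"]), sig(["a"], agent="B"), ["a", "b"])


class TestHypergeometricP:
    def test_small_case_exact_third(self):
        t = ContingencyTable(2, 1, 2, 5)  # N=10, |A|=3, |B|=4, a=2
        assert hypergeometric_p(t) == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("N,kA,kB,a", [(10, 3, 4, 2), (8, 4, 4, 3), (12, 5, 6, 1), (9, 2, 7, 2)])
    def test_matches_enumeration_oracle(self, N, kA, kB, a):
        t = ContingencyTable(a, kA - a, kB - a, N - kA - kB + a)
        assert hypergeometric_p(t) == pytest.approx(enum_hyper_tail(N, kA, kB, a), abs=1e-12)

    def test_degenerate_support(self):
        t = ContingencyTable(5, 0, 0, 0)  # A = B = U
        assert hypergeometric_p(t) == 1.0

    def test_nonincreasing_in_a(self):
        ps = [
            hypergeometric_p(ContingencyTable(a, 6 - a, 8 - a, 6 + a))
            for a in range(0, 7)
        ]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_depletion_tail(self):
        t = ContingencyTable(0, 3, 4, 3)
        assert hypergeometric_p(t, alternative="less") == pytest.approx(
            stats.hypergeom.cdf(0, 10, 4, 3)
        )


class TestPermutationP:
    def test_converges_to_exact_small_case(self):
        U = [f"u{i}" for i in range(10)]
        A, B = sig(U[:3]), sig(U[1:5], agent="B")  # overlap = 2
        n_perm = 100_000
        p = permutation_overlap_p(A, B, U, n_perm=n_perm, seed=7)
        se = np.sqrt((1 / 3) * (2 / 3) / n_perm)
        assert abs(p - 1 / 3) < 3 * se

    def test_maximal_overlap_gives_p_one(self):
        U = list("abcde")
        p = permutation_overlap_p(sig(U), sig(U, agent="B"), U, n_perm=500, seed=0)
        assert p == 1.0

    def test_reproducible_given_seed(self):
        U = [f"u{i}" for i in range(50)]
        A, B = sig(U[:10]), sig(U[5:25], agent="B")
        p1 = permutation_overlap_p(A, B, U, n_perm=2000, seed=42)
        p2 = permutation_overlap_p(A, B, U, n_perm=2000, seed=42)
        assert p1 == p2
        assert permutation_overlap_p(A, B, U, n_perm=2000, seed=43) != p1

    def test_resample_both_same_null(self):
        U = [f"u{i}" for i in range(10)]
        A, B = sig(U[:3]), sig(U[1:5], agent="B")
        p = permutation_overlap_p(A, B, U, n_perm=20_000, seed=3, resample="both")
        assert abs(p - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / 20_000)

    def test_invalid_n_perm(self):
        U = list("abc")
        with pytest.raises(ValueError):
            permutation_overlap_p(sig("a"), sig("b", agent="B"), U, n_perm=0)

    def test_null_pvalues_valid_and_nondegenerate(self):
        """With A random and no association the p-value is valid.

        At this universe size the overlap statistic is coarsely discrete,
        so the null p is sub-uniform rather than exactly uniform: its
        empirical CDF must never significantly exceed the uniform CDF
        (validity), while staying far from degenerate.
        """
        rng = np.random.default_rng(0)
        U = [f"u{i}" for i in range(60)]
        B = sig(U[:20], agent="B")
        ps = []
        for i in range(300):
            kA = int(rng.integers(6, 25))
            A = sig(rng.choice(U, size=kA, replace=False))
            ps.append(permutation_overlap_p(A, B, U, n_perm=499, seed=i))
        assert stats.ks_1samp(ps, stats.uniform.cdf, alternative="greater").pvalue > 0.01
        assert 0.3 < np.median(ps) < 0.8
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 300)


class TestOddsRatioJaccard:
    def test_printed_counts_arithmetic(self):
        odds, jac = odds_ratio_and_jaccard(ContingencyTable(28, 44, 336, 827))
        assert odds == pytest.approx(28 * 827 / (44 * 336), rel=1e-12)
        assert jac == pytest.approx(28 / 408, rel=1e-12)

    def test_symmetric_cells_give_unit_odds(self):
        odds, jac = odds_ratio_and_jaccard(ContingencyTable(3, 3, 3, 3))
        assert odds == 1.0
        assert jac == pytest.approx(1 / 3)

    def test_haldane_correction(self):
        odds, _ = odds_ratio_and_jaccard(ContingencyTable(2, 0, 1, 7))
        assert odds == pytest.approx((2.5 * 7.5) / (0.5 * 1.5))

    def test_swap_invariance(self):
        U = [f"u{i}" for i in range(30)]
        A, B = sig(U[:10]), sig(U[5:20], agent="B")
        rAB = compare_signatures(A, B, U, n_perm=10, seed=0)
        rBA = compare_signatures(B, A, U, n_perm=10, seed=0)
        assert rAB.odds_ratio == pytest.approx(rBA.odds_ratio)
        assert rAB.jaccard == pytest.approx(rBA.jaccard)

    def test_percent_overlap_both_conventions(self):
        res = compare_signatures(
            sig([f"u{i}" for i in range(10)]),
            sig([f"u{i}" for i in range(5, 25)], agent="B"),
            [f"u{i}" for i in range(50)],
            n_perm=10,
            seed=0,
        )
        pct = res.percent_overlap()
        assert pct["of_smaller_set"] == pytest.approx(100 * 5 / 10)
        assert pct["of_union"] == pytest.approx(100 * 5 / 25)


class TestBackgroundAgreement:
    def test_closed_forms(self):
        U = [f"g{i}" for i in range(10)]
        # uA = 0.6, uB = 0.7 -> p0 = 0.42 + 0.12 = 0.54
        tA = make_table(U, [1] * 6 + [-1] * 4, [0.5] * 10)
        tB = make_table(U, [1] * 7 + [-1] * 3, [0.5] * 10, agent="B")
        assert background_agreement_prob(tA, tB, U) == pytest.approx(0.54)

    def test_all_up_gives_one(self):
        U = ["a", "b"]
        t = make_table(U, [1.0, 2.0], [0.5, 0.5])
        assert background_agreement_prob(t, t, U) == 1.0

    def test_half_up_gives_half_regardless_of_other(self):
        U = [f"g{i}" for i in range(8)]
        tA = make_table(U, [1, -1] * 4, [0.5] * 8)
        tB = make_table(U, [1] * 7 + [-1], [0.5] * 8, agent="B")
        assert background_agreement_prob(tA, tB, U) == pytest.approx(0.5)

    def test_zero_lfc_excluded(self):
        U = ["a", "b", "c"]
        tA = make_table(U, [1.0, 0.0, -1.0], [0.5] * 3)
        tB = make_table(U, [1.0, 1.0, 1.0], [0.5] * 3, agent="B")
        # uA over {a, c} = 0.5
        assert background_agreement_prob(tA, tB, U) == pytest.approx(0.5)

    def test_empty_universe_errors(self):
        t = make_table(["a"], [1.0], [0.5])
        with pytest.raises(ValueError):
            background_agreement_prob(t, t, [])


class TestDirectionalConcordance:
    def test_three_of_three_fair_coin(self):
        A = sig("abc", {"a": 1, "b": -1, "c": 1})
        B = sig("abc", {"a": 1, "b": -1, "c": 1}, agent="B")
        res = directional_concordance(A, B, 0.5)
        assert res.p_binom == pytest.approx(0.125)

    def test_binomial_tail_matches_simulation_oracle(self):
        """n=28, k=25, p0=0.52 against a Bernoulli simulation."""
        n, k, p0 = 28, 25, 0.52
        ids = [f"g{i}" for i in range(n)]
        dirA = {g: 1 for g in ids}
        dirB = {g: (1 if i < k else -1) for i, g in enumerate(ids)}
        res = directional_concordance(sig(ids, dirA), sig(ids, dirB, agent="B"), p0)
        assert res.n_overlap == n and res.k_agree == k
        rng = np.random.default_rng(2024)
        n_rep = 200_000
        sim = (rng.random((n_rep, n)) < p0).sum(axis=1)
        mc = (sim >= k).mean()
        se = np.sqrt(max(mc, 1e-9) * (1 - mc) / n_rep)
        assert abs(res.p_binom - mc) < 4 * se + 1e-6
        assert res.p_binom == pytest.approx(float(stats.binom.sf(k - 1, n, p0)))

    def test_degenerate_p0(self):
        A = sig("ab", {"a": 1, "b": 1})
        B = sig("ab", {"a": 1, "b": 1}, agent="B")
        assert directional_concordance(A, B, 1.0).p_binom == 1.0
        assert directional_concordance(A, B, 0.0).p_binom == 0.0

    def test_empty_overlap(self):
        res = directional_concordance(sig("ab"), sig("cd", agent="B"), 0.5)
        assert res.n_overlap == 0 and res.p_binom == 1.0

    def test_false_positive_rate_near_nominal(self):
        """Independent random directions reject at ~alpha."""
        rng = np.random.default_rng(7)
        n_rep, n, alpha = 500, 40, 0.05
        rejects = 0
        ids = [f"g{i}" for i in range(n)]
        for _ in range(n_rep):
            dA = {g: int(s) for g, s in zip(ids, rng.choice([-1, 1], n))}
            dB = {g: int(s) for g, s in zip(ids, rng.choice([-1, 1], n))}
            if directional_concordance(sig(ids, dA), sig(ids, dB, agent="B"), 0.5).p_binom < alpha:
                rejects += 1
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejects / n_rep < alpha + 3 * se  # exact test is valid (possibly conservative)
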