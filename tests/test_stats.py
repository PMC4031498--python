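"""Exact small-sample behaviour of the statistical tests against enumeration oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from mirsites import stats


def hypergeom_tail_oracle(N, K, n, x, tail):
    """Full enumeration over all C(N, n) draws from an urn with K marked balls."""
    total = comb(N, n)
    def p_eq(k):
        return comb(K, k) * comb(N - K, n - k) / total
    ks = range(x, min(K, n) + 1) if tail == "greater" else range(0, x + 1)
    return sum(p_eq(k) for k in ks)


class TestHypergeometric:
    def test_worked_example(self):
        result = stats.hypergeometric_enrichment(10, 5, 4, 4, "greater")
        assert result.p_value == pytest.approx(5 / 210, abs=1e-9)

    def test_zero_overlap_depletion_with_empty_set(self):
        assert stats.hypergeometric_enrichment(10, 0, 4, 0, "less").p_value == pytest.approx(1.0)

    def test_set_equals_universe(self):
        assert stats.hypergeometric_enrichment(10, 10, 4, 4, "greater").p_value == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            stats.hypergeometric_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError):
            stats.hypergeometric_enrichment(10, 12, 4, 2)

    def test_matches_enumeration_for_small_universes(self):
        for N in range(2, 13):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    for x in range(max(0, K + n - N), min(K, n) + 1):
                        for tail in ("greater", "less"):
                            got = stats.hypergeometric_enrichment(N, K, n, x, tail).p_value
                            assert got == pytest.approx(
                                hypergeom_tail_oracle(N, K, n, x, tail), abs=1e-9)

    def test_tail_identity(self):
        for N in range(2, 13):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    for x in range(max(1, K + n - N), min(K, n) + 1):
                        p_ge = stats.hypergeometric_enrichment(N, K, n, x, "greater").p_value
                        p_le = stats.hypergeometric_enrichment(N, K, n, x - 1, "less").p_value
                        assert p_ge + p_le == pytest.approx(1.0, abs=1e-9)

    def test_log_space_survives_extreme_tails(self):
        p = stats.hypergeometric_enrichment(20000, 500, 500, 480, "greater").p_value
        assert 0 < p < 1e-300 or p == 0.0  # far beyond double PMF underflow, no NaN


def ranksum_exact_oracle(x, y, tail="two_sided"):
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n)]
    if tail == "two_sided":
        return np.mean([abs(s - mu) >= abs(w_obs - mu) - 1e-12 for s in sums])
    raise NotImplementedError


class TestRankSum:
    def test_worked_example(self):
        result = stats.wilcoxon_rank_sum([1, 2], [3, 4])
        assert result.statistic == 3.0
        assert result.p_value == pytest.approx(2 / 6, abs=1e-9)

    def test_identical_multisets_p_one(self):
        result = stats.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert result.p_value == pytest.approx(1.0)

    def test_degenerate_constant_samples(self):
        result = stats.wilcoxon_rank_sum([5, 5], [5, 5, 5])
        assert result.degenerate and result.p_value == 1.0

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.integers(0, 5, size=int(rng.integers(2, 7))).astype(float)
            y = rng.integers(0, 5, size=int(rng.integers(2, 7))).astype(float)
            got = stats.wilcoxon_rank_sum(x, y).p_value
            assert got == pytest.approx(ranksum_exact_oracle(x, y), abs=1e-9)

    def test_approximation_close_to_enumeration(self):
        # n + m = 17 forces the normal path; oracle enumerates C(17, 9) splits
        x = np.arange(9, dtype=float) + 1.5  # shifted copy of y
        y = np.arange(8, dtype=float)
        approx = stats.wilcoxon_rank_sum(x, y).p_value
        assert stats.wilcoxon_rank_sum(x, y).method == "rank-sum (normal approx)"
        assert approx == pytest.approx(ranksum_exact_oracle(x, y), abs=0.01)

    def test_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=25)
        y = rng.normal(0.5, size=30)
        ours = stats.wilcoxon_rank_sum(x, y).p_value
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_one_sided_tails_are_complementary(self):
        x = [1.0, 2.0, 6.0]
        y = [3.0, 4.0, 5.0]
        greater = stats.wilcoxon_rank_sum(x, y, "greater").p_value
        less = stats.wilcoxon_rank_sum(x, y, "less").p_value
        assert greater + less >= 1.0  # both include the observed point mass


def ks_d_oracle(x, y):
    pooled = sorted(set(list(x) + list(y)))
    d = 0.0
    for t in pooled:
        f_x = sum(v <= t for v in x) / len(x)
        f_y = sum(v <= t for v in y) / len(y)
        d = max(d, abs(f_x - f_y))
    return d


class TestKS:
    def test_identical_samples(self):
        result = stats.ks_two_sample([1, 2, 3], [1, 2, 3])
        assert result.statistic == 0.0 and result.p_value == pytest.approx(1.0)

    def test_fully_separated(self):
        assert stats.ks_two_sample([1, 2, 3], [10, 11]).statistic == 1.0

    def test_worked_example_against_ecdf_enumeration(self):
        x, y = [1, 2, 3], [2.5, 3.5]
        result = stats.ks_two_sample(x, y)
        assert result.statistic == pytest.approx(ks_d_oracle(x, y), abs=1e-12)

    def test_d_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(3, 40)))
            y = rng.normal(0.3, size=int(rng.integers(3, 40)))
            assert stats.ks_two_sample(x, y).statistic == pytest.approx(
                ks_d_oracle(x, y), abs=1e-12)

    def test_asymptotic_p_close_to_scipy(self):
        # scipy's asymptotic mode carries a finite-sample correction on top of
        # the classical Kolmogorov limit, so agreement is approximate
        rng = np.random.default_rng(11)
        x = rng.normal(size=150)
        y = rng.normal(0.2, size=120)
        ours = stats.ks_two_sample(x, y)  # n*m > 10000 -> asymptotic
        assert ours.method == "ks (asymptotic)"
        ref = sps.ks_2samp(x, y, method="asymp").pvalue
        assert ours.p_value == pytest.approx(ref, rel=0.2)


class TestSpearman:
    def test_monotone_pairs(self):
        assert stats.spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert stats.spearman([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        assert stats.spearman([1, 1, 1], [1, 2, 3]) is None

    def test_tied_case_matches_midrank_formula(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [3.0, 3.0, 1.0, 5.0, 4.0]
        rank_x = sps.rankdata(x)
        rank_y = sps.rankdata(y)
        oracle = np.corrcoef(rank_x, rank_y)[0, 1]
        assert stats.spearman(x, y) == pytest.approx(oracle, abs=1e-12)


def test_benjamini_hochberg_helper_monotone():
    q = stats.benjamini_hochberg([0.001, 0.01, 0.02, 0.8])
    assert (np.diff(q) >= -1e-12).all() and q[0] >= 0.001
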