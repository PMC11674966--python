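import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaburden import (
    ChromosomeCountSample,
    FociCountSample,
    TwoByTwoTable,
    amplified_fraction,
    fisher_exact_two_sided,
    mann_whitney_u,
    summarize_chromosome_counts,
    unpaired_t_test,
    wilcoxon_signed_rank,
)
from cnaburden.stats import format_p

from oracles import fisher_oracle, mann_whitney_exact_oracle, wilcoxon_exact_oracle


class TestFisher:
    @pytest.mark.parametrize(
        "table,printed",
        [
            # LUAD clinicopathological cross-tabulations
            ([[89, 148], [5, 26]], 0.0262),   # pT
            ([[77, 120], [15, 51]], 0.0171),  # pN
            ([[85, 134], [9, 40]], 0.0076),   # TNM stage
            ([[29, 45], [65, 129]], 0.3936),  # age
            # LUSC
            ([[42, 30], [6, 20]], 0.0027),    # pT
            ([[39, 27], [9, 23]], 0.0051),    # TNM stage
            ([[32, 30], [16, 18]], 0.8312),   # pN
            ([[3, 3], [45, 47]], 1.0000),     # sex
        ],
    )
    def test_reproduces_published_cross_tabulations(self, table, printed):
        res = fisher_exact_two_sided(table)
        assert round(res.p_value, 4) == printed
        assert format_p(res.p_value) == f"{printed:.4f}"

    def test_symmetric_table(self):
        assert fisher_exact_two_sided([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        cases = [(5, 0, 0, 5), (3, 7, 8, 2), (1, 9, 9, 1), (10, 2, 3, 12), (2, 2, 2, 2)]
        for a, b, c, d in cases:
            assert fisher_exact_two_sided([[a, b], [c, d]]).p_value == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-7
            )

    def test_diagonal_table_exact_value(self):
        # 2 / C(10,5) = 0.00793650...
        assert fisher_exact_two_sided([[5, 0], [0, 5]]).p_value == pytest.approx(
            2 / 252, rel=1e-9
        )

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = fisher_exact_two_sided([[0, 0], [5, 7]])
        assert res.p_value == 1.0

    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) > 0))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_invariances(self, cells):
        """p is invariant under row swap, column swap, and transpose."""
        a, b, c, d = cells
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        p = fisher_exact_two_sided([[a, b], [c, d]]).p_value
        for variant in ([[c, d], [a, b]], [[b, a], [d, c]], [[a, c], [b, d]]):
            assert fisher_exact_two_sided(variant).p_value == pytest.approx(p, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 500)
        y = rng.normal(1, 1, 500)
        assert mann_whitney_u(x, y).p_value < 1e-4

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n1, n2 = rng.integers(2, 7, size=2)
            pool = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = list(pool[:n1]), list(pool[n1:])
            assert mann_whitney_u(x, y, mode="exact").p_value == pytest.approx(
                mann_whitney_exact_oracle(x, y)
            )

    def test_exact_vs_normal_agreement(self):
        """Regression guard: for tie-free samples with min(n) ≤ 8 the
        corrected normal approximation stays within 0.02 of exact."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            n1 = int(rng.integers(4, 9))
            n2 = int(rng.integers(4, 15))
            pool = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pool[:n1], pool[n1:]
            p_exact = mann_whitney_u(x, y, mode="exact").p_value
            p_norm = mann_whitney_u(x, y, mode="normal").p_value
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])

    def test_two_sided_at_least_one_sided(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        from scipy.stats import mannwhitneyu

        p2 = mann_whitney_u(x, y).p_value
        p1 = min(
            mannwhitneyu(x, y, alternative="less").pvalue,
            mannwhitneyu(x, y, alternative="greater").pvalue,
        )
        assert p2 >= p1


class TestWilcoxon:
    def test_exact_three_pairs(self):
        res = wilcoxon_signed_rank([(1, 2), (2, 4), (3, 6)])
        assert res.p_value == pytest.approx(0.25)

    def test_balanced_differences_p_one(self):
        res = wilcoxon_signed_rank([(0, 1), (1, 0)])
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([(1, 1), (2, 2)])

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([(1, 2), (2, 4), (3, 6), (5, 5)])
        assert res.n1 == 3
        assert res.p_value == pytest.approx(0.25)

    def test_matched_cohort_strong_shift(self):
        """83 matched tumor/normal pairs with tumor ≫ normal."""
        rng = np.random.default_rng(17)
        normal = np.exp(rng.normal(3.6, 0.5, 83))
        tumor = normal * np.exp(rng.normal(1.5, 0.5, 83))
        res = wilcoxon_signed_rank(list(zip(normal, tumor)))
        assert res.p_value < 1e-4

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(3, 11))
            diffs = rng.permutation(np.arange(1.0, n + 1)) * rng.choice([-1, 1], n)
            pairs = [(0.0, d) for d in diffs]
            assert wilcoxon_signed_rank(pairs, mode="exact").p_value == pytest.approx(
                wilcoxon_exact_oracle(list(diffs))
            )


class TestTTest:
    def test_identical_groups(self):
        res = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_clear_separation(self):
        assert unpaired_t_test([10, 11, 12], [20, 21, 22]).p_value < 0.01

    def test_welch_vs_permutation(self):
        rng = np.random.default_rng(31)
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 2, 15)
        p_welch = unpaired_t_test(x, y).p_value
        # permutation reference on the mean difference
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        count = 0
        for _ in range(4000):
            perm = rng.permutation(pooled)
            if abs(perm[:15].mean() - perm[15:].mean()) >= obs:
                count += 1
        assert abs(p_welch - count / 4000) < 0.05

    def test_degenerate_zero_variance(self):
        res = unpaired_t_test([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_pooled_variant_available(self):
        res = unpaired_t_test([1, 2, 3], [2, 3, 4], equal_var=True)
        assert res.method == "t_test_pooled"

    def test_too_small_group_errors(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1], [2, 3])


class TestAssaySummaries:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([2, 2, 4, 5, 6], 40.0),
            ([4, 4, 4], 0.0),  # exactly four foci is normal
            ([5], 100.0),
        ],
    )
    def test_amplified_fraction(self, counts, expected):
        assert amplified_fraction(counts) == pytest.approx(expected)
        assert amplified_fraction(FociCountSample(tuple(counts))) == pytest.approx(expected)

    def test_amplified_fraction_empty_errors(self):
        with pytest.raises(ValueError):
            amplified_fraction([])

    def test_chromosome_summary_medians(self):
        samples = [
            ChromosomeCountSample((98, 100, 102), "baseline"),
            ChromosomeCountSample((98, 100, 102), "same"),
        ]
        summary, comps = summarize_chromosome_counts(samples)
        assert summary.loc[summary.condition == "baseline", "median"].item() == 100
        assert comps.loc[0, "p_value"] == pytest.approx(1.0, abs=0.05)

    def test_unknown_condition_in_pair_list_errors(self):
        samples = [
            ChromosomeCountSample((98, 100), "a"),
            ChromosomeCountSample((99, 101), "b"),
        ]
        with pytest.raises(ValueError, match="ghost"):
            summarize_chromosome_counts(samples, comparisons=[("a", "ghost")])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            FociCountSample((-1, 2))
        with pytest.raises(ValueError):
            ChromosomeCountSample((0,), "x")
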