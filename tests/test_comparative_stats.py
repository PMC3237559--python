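"""Elevation index, sign test, Wilcoxon chi-square, CIs, Spearman, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import radcon as rc
from radcon.comparative_stats import (
    GeneComparison,
    build_comparisons,
    pct_higher_a,
    summarize_by_category,
    summarize_comparison,
)


def binomial_tail_oracle(a, n):
    """P(X >= a) for X ~ Binomial(n, 1/2), by direct enumeration."""
    return sum(math.comb(n, k) for k in range(a, n + 1)) / 2**n


class TestElevationIndex:
    def test_equal_ratios_give_one(self):
        assert rc.elevation_index(0.7, 0.7) == 1.0

    def test_undefined_denominator_excluded_with_reason(self):
        comps, excluded = build_comparisons({"g1": 0.5, "g2": 0.8}, {"g1": 0.4, "g2": None})
        assert [c.gene for c in comps] == ["g1"]
        assert "g2" in excluded

    def test_median_of_indices_differs_from_ratio_of_medians(self):
        # 3-gene counterexample
        a = {"g1": 2.0, "g2": 3.0, "g3": 10.0}
        b = {"g1": 1.0, "g2": 4.0, "g3": 2.0}
        comps, _ = build_comparisons(a, b)
        per_gene_median = np.median([c.elevation for c in comps])
        ratio_of_medians = np.median(list(a.values())) / np.median(list(b.values()))
        assert per_gene_median != ratio_of_medians


class TestSignTest:
    def test_symmetric_two_sided_capped_at_one(self):
        assert rc.sign_test(5, 5, "two-sided").p == 1.0

    def test_ten_to_zero_one_sided(self):
        assert rc.sign_test(10, 0, "one-sided-a-greater").p == pytest.approx(2**-10)

    def test_matches_enumeration_oracle_up_to_n_30(self):
        for n in range(1, 31):
            for a in range(n + 1):
                got = rc.sign_test(a, n - a, "one-sided-a-greater").p
                exact = binomial_tail_oracle(a, n)
                assert got == pytest.approx(exact, rel=1e-10)
                two = rc.sign_test(a, n - a, "two-sided").p
                expected_two = min(1.0, 2.0 * min(exact, 1.0 - binomial_tail_oracle(a + 1, n)))
                assert two == pytest.approx(expected_two, rel=1e-10)

    def test_null_calibration_at_alpha_01(self):
        # one-sided test rejects at the nominal rate under the null
        rng = np.random.default_rng(0)
        n_genes, reps, alpha = 256, 1000, 0.01
        rejections = 0
        for a in rng.binomial(n_genes, 0.5, size=reps):
            if rc.sign_test(int(a), n_genes - int(a), "one-sided-a-greater").p < alpha:
                rejections += 1
        # binomial tolerance around 1% of 1000
        assert rejections <= 25


class TestWilcoxonChiSquare:
    def test_identical_vectors_give_zero(self):
        r = rc.wilcoxon_chisq([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_small_vector_matches_manual_ranking(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [0.5, 2.5, 2.0, 3.0, 4.0, 7.0]
        d = np.array(a) - np.array(b)  # [.5, -.5, 1, 1, 1, -1]
        # |d| ranks (midranks): .5 -> 1.5, 1 -> 4.5
        w_plus = 1.5 + 4.5 + 4.5 + 4.5
        n = 6
        mean = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        for t in (2, 4):  # tie groups of sizes 2 and 4
            var -= (t**3 - t) / 48
        expected = (w_plus - mean) ** 2 / var
        r = rc.wilcoxon_chisq(a, b)
        assert r.statistic == pytest.approx(expected)
        assert r.p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_statistic_grows_with_n_under_location_shift(self):
        rng = np.random.default_rng(1)
        stats_by_n = []
        for n in (20, 50, 100):
            vals = [
                rc.wilcoxon_chisq(rng.normal(0.2, 1, n) , np.zeros(n)).statistic
                for _ in range(40)
            ]
            stats_by_n.append(np.mean(vals))
        assert stats_by_n[0] < stats_by_n[1] < stats_by_n[2]


class TestSummarizeElevation:
    def test_constant_vector_zero_width_ci(self):
        s = rc.summarize_elevation([2.0, 2.0, 2.0])
        assert s.mean == 2.0
        assert s.ci[0.95] == (2.0, 2.0)
        assert s.lower_bound_exceeds_1[0.95]

    def test_sample_centered_at_one_does_not_exceed_one(self):
        rng = np.random.default_rng(2)
        s = rc.summarize_elevation(rng.normal(1.0, 0.1, 100))
        assert not s.lower_bound_exceeds_1[0.99]

    def test_ci_coverage_on_lognormal_indices(self):
        rng = np.random.default_rng(3)
        mu, sigma, n = 0.0, 0.5, 200
        true_mean = math.exp(mu + sigma**2 / 2)
        covered = 0
        for _ in range(1000):
            x = rng.lognormal(mu, sigma, n)
            lo, hi = rc.summarize_elevation(x, levels=(0.99,)).ci[0.99]
            covered += lo <= true_mean <= hi
        assert covered >= 975  # ~99% nominal with Monte-Carlo slack


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert rc.spearman_assoc(x, [2, 4, 6, 8, 10]).statistic == pytest.approx(1.0)
        assert rc.spearman_assoc(x, [10, 8, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_tied_data_matches_manual_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0]
        y = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0]

        def midranks(v):
            return stats.rankdata(v)

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rc.spearman_assoc(x, y).statistic == pytest.approx(expected)

    def test_constant_vector_signals(self):
        with pytest.raises(ValueError):
            rc.spearman_assoc([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


def _toy_grid(rng, effect=0.0, reps=5):
    rows = []
    for ftab in ("x", "y", "z"):
        for om in (0.3, 0.6):
            for t in (0.5, 1.0, 4.0):
                for k in (1.0, 2.0, 5.0, 10.0):
                    for _ in range(reps):
                        shift = effect if ftab == "x" else 0.0
                        rows.append(
                            dict(freq_table=ftab, omega=om, t=t, kappa=k,
                                 ratio=rng.normal(1.0 + shift, 0.1))
                        )
    return pd.DataFrame(rows)


class TestAnova:
    def test_degrees_of_freedom(self):
        table = rc.anova_factorial(_toy_grid(np.random.default_rng(4)))
        assert table.loc["freq_table", "df"] == 2
        assert table.loc["kappa", "df"] == 3
        assert table.loc["t", "df"] == 2
        assert table.loc["omega", "df"] == 1

    def test_balanced_two_factor_sums_of_squares_match_hand_computation(self):
        # 2x2 balanced design, 2 reps, known group means
        df = pd.DataFrame(
            dict(
                freq_table=["a"] * 4 + ["b"] * 4,
                kappa=[1, 1, 2, 2] * 2,
                t=[1.0] * 8,
                omega=[0.3] * 8,
                ratio=[1.0, 1.2, 1.4, 1.6, 2.0, 2.2, 2.4, 2.6],
            )
        )
        table = rc.anova_factorial(df, factors=("freq_table", "kappa"))
        grand = df["ratio"].mean()
        ss_table = sum(
            4 * (df[df.freq_table == lvl]["ratio"].mean() - grand) ** 2 for lvl in ("a", "b")
        )
        ss_kappa = sum(
            4 * (df[df.kappa == lvl]["ratio"].mean() - grand) ** 2 for lvl in (1, 2)
        )
        assert table.loc["freq_table", "sum_sq"] == pytest.approx(ss_table)
        assert table.loc["kappa", "sum_sq"] == pytest.approx(ss_kappa)
        total = ((df["ratio"] - grand) ** 2).sum()
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-6)

    def test_null_f_statistics_within_central_99_range(self):
        table = rc.anova_factorial(_toy_grid(np.random.default_rng(5), reps=2))
        for factor in ("freq_table", "kappa", "t", "omega"):
            f = table.loc[factor, "F"]
            dfn = table.loc[factor, "df"]
            dfd = table.loc["Residual", "df"]
            lo, hi = stats.f.ppf([0.005, 0.995], dfn, dfd)
            assert lo <= f <= hi

    def test_signal_factor_detected(self):
        table = rc.anova_factorial(_toy_grid(np.random.default_rng(6), effect=0.5))
        assert table.loc["freq_table", "PR(>F)"] < 1e-10
        assert table.loc["omega", "PR(>F)"] > 0.001


class TestComparisonSummary:
    def test_percentages_from_counts(self):
        assert pct_higher_a(196, 60) == pytest.approx(76.5625)
        assert round(pct_higher_a(196, 60), 1) == 76.6

    def test_multi_label_gene_counts_in_both_categories(self):
        comps = [
            GeneComparison("g1", 1.2, 1.0, 1.2, ("Metabolism", "Transport")),
            GeneComparison("g2", 1.4, 1.0, 1.4, ("Metabolism",)),
            GeneComparison("g3", 1.1, 1.0, 1.1, ("Transport",)),
            GeneComparison("g4", 0.9, 1.0, 0.9, ()),
            GeneComparison("g5", 0.8, 1.0, 0.8, ()),
        ]
        by_cat = summarize_by_category(comps)
        assert by_cat["Metabolism"].n == 2
        assert by_cat["Transport"].n == 2
        assert by_cat["Unclassified"].n == 2

    def test_single_category_reproduces_global_summary(self):
        comps = [
            GeneComparison(f"g{i}", 1.0 + 0.1 * i, 1.0, 1.0 + 0.1 * i, ("OnlyOne",))
            for i in range(10)
        ]
        global_summary = summarize_comparison(comps, levels=(0.95, 0.99))
        by_cat = summarize_by_category(comps)
        assert by_cat["OnlyOne"] == global_summary

    def test_ties_excluded_from_counts(self):
        comps = [
            GeneComparison("g1", 1.0, 1.0, 1.0),
            GeneComparison("g2", 2.0, 1.0, 2.0),
            GeneComparison("g3", 0.5, 1.0, 0.5),
        ]
        s = summarize_comparison(comps)
        assert s.n_ties == 1
        assert s.n_higher_a == 1 and s.n_higher_b == 1
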