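"""Comparative statistics for paired-gene D_r/D_c comparisons.

Two genome pairs (A and B) that share a set of orthologs are compared gene by
gene: the per-gene *elevation index* is (D_r/D_c in pair A)/(D_r/D_c in
pair B), computed for each gene *before* any summarisation.  Departure from
parity is tested with an exact binomial sign test on the higher-in-A vs
higher-in-B counts and a Wilcoxon rank test whose significance is evaluated
through a 1-df chi-square approximation.  A main-effects factorial ANOVA
quantifies the sensitivity of simulated D_r/D_c estimates to the simulation
factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.formula.api import ols


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p: float
    method: str
    alternative: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# Elevation index


@dataclass(frozen=True)
class GeneComparison:
    gene: str
    ratio_a: float
    ratio_b: float
    elevation: float
    categories: tuple[str, ...] = ()


def elevation_index(ratio_a: float, ratio_b: float) -> float:
    """Per-gene ratio of the two D_r/D_c values; > 1 means higher in pair A."""
    if not (np.isfinite(ratio_a) and np.isfinite(ratio_b)):
        raise ValueError("ratios must be finite")
    if ratio_b <= 0:
        raise ValueError("ratio_b must be positive")
    return ratio_a / ratio_b


def build_comparisons(
    ratios_a: Mapping[str, float | None],
    ratios_b: Mapping[str, float | None],
    categories: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[GeneComparison], dict[str, str]]:
    """Join per-gene ratios from two genome pairs on gene id.

    Returns the usable comparisons plus an exclusion record mapping each
    dropped gene to the reason (missing or undefined ratio).
    """
    comparisons: list[GeneComparison] = []
    excluded: dict[str, str] = {}
    for gene in sorted(set(ratios_a) | set(ratios_b)):
        ra = ratios_a.get(gene)
        rb = ratios_b.get(gene)
        if ra is None or rb is None or not np.isfinite(ra) or not np.isfinite(rb):
            excluded[gene] = "ratio undefined in pair A" if ra is None else "ratio undefined in pair B"
            continue
        if rb <= 0:
            excluded[gene] = "ratio_b not positive"
            continue
        labels = tuple(categories.get(gene, ())) if categories else ()
        comparisons.append(GeneComparison(gene, ra, rb, ra / rb, labels))
    return comparisons, excluded


# ---------------------------------------------------------------------------
# Tests


def sign_test(
    n_higher_a: int, n_higher_b: int, alternative: str = "one-sided-a-greater"
) -> StatTestResult:
    """Sign test at p = 0.5 on untied higher-in-A/B counts.

    ``one-sided-a-greater`` and ``two-sided`` are exact binomial tail
    probabilities (the two-sided p doubles the smaller tail, capped at 1).
    ``two-sided-normal`` is the large-sample normal approximation
    z = (a - n/2)/(sqrt(n)/2) without continuity correction, the variant
    some statistics packages report for two-way sign tests.
    """
    if n_higher_a < 0 or n_higher_b < 0:
        raise ValueError("counts must be non-negative")
    n = n_higher_a + n_higher_b
    if n < 1:
        raise ValueError("need at least one untied observation")
    upper = float(stats.binom.sf(n_higher_a - 1, n, 0.5))  # P(X >= a)
    lower = float(stats.binom.cdf(n_higher_a, n, 0.5))  # P(X <= a)
    method = "exact binomial sign test"
    if alternative == "one-sided-a-greater":
        p = upper
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(upper, lower))
    elif alternative == "two-sided-normal":
        z = (n_higher_a - n / 2.0) / (math.sqrt(n) / 2.0)
        p = 2.0 * float(stats.norm.sf(abs(z)))
        method = "normal-approximation sign test"
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return StatTestResult(
        statistic=float(n_higher_a), p=p, method=method, alternative=alternative,
    )


def wilcoxon_chisq(
    values_a: Sequence[float],
    values_b: Sequence[float],
    mode: str = "signed-rank",
) -> StatTestResult:
    """Wilcoxon rank test with a 1-df chi-square approximation.

    ``signed-rank`` treats the inputs as paired per-gene values (zero
    differences dropped, midranks for ties); ``rank-sum`` treats them as two
    independent groups.  The chi-square is (statistic - mean)^2 / variance
    under the null, referred to a chi-square with 1 df.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if mode == "signed-rank":
        if a.shape != b.shape:
            raise ValueError("paired vectors must have equal length")
        d = a - b
        d = d[d != 0]
        n = len(d)
        if n == 0:
            return StatTestResult(0.0, 1.0, "Wilcoxon signed-rank (chi-square approx.)")
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
        if var <= 0:
            return StatTestResult(0.0, 1.0, "Wilcoxon signed-rank (chi-square approx.)")
        chisq = (w_plus - mean) ** 2 / var
        method = "Wilcoxon signed-rank (chi-square approx.)"
    elif mode == "rank-sum":
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n1, n2 = len(a), len(b)
        w = float(ranks[:n1].sum())
        mean = n1 * (n1 + n2 + 1) / 2.0
        var = n1 * n2 * (n1 + n2 + 1) / 12.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        nt = n1 + n2
        var -= n1 * n2 * float(((tie_counts**3 - tie_counts)).sum()) / (12.0 * nt * (nt - 1))
        if var <= 0:
            return StatTestResult(0.0, 1.0, "Wilcoxon rank-sum (chi-square approx.)")
        chisq = (w - mean) ** 2 / var
        method = "Wilcoxon rank-sum (chi-square approx.)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = float(stats.chi2.sf(chisq, df=1))
    return StatTestResult(float(chisq), p, method)


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> StatTestResult:
    """Spearman rank correlation (midrank ties, t-approximation p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return StatTestResult(float(rho), float(p), "Spearman rank correlation")


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class ElevationSummary:
    n: int
    mean: float
    median: float
    ci: dict[float, tuple[float, float]]
    lower_bound_exceeds_1: dict[float, bool]


def summarize_elevation(
    indices: Sequence[float],
    levels: Sequence[float] = (0.95, 0.99),
    method: str = "t",
    n_boot: int = 10_000,
    seed: int = 0,
) -> ElevationSummary:
    """Mean, median and confidence intervals of the mean of per-gene indices.

    ``method='t'`` gives the normal-theory t interval; ``method='bootstrap'``
    a seeded BCa bootstrap.
    """
    x = np.asarray(indices, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    ci: dict[float, tuple[float, float]] = {}
    for level in levels:
        if method == "t":
            sem = stats.sem(x)
            if sem == 0:
                ci[level] = (mean, mean)
            else:
                lo, hi = stats.t.interval(level, df=n - 1, loc=mean, scale=sem)
                ci[level] = (float(lo), float(hi))
        elif method == "bootstrap":
            res = stats.bootstrap(
                (x,), np.mean, confidence_level=level, n_resamples=n_boot,
                method="BCa", rng=np.random.default_rng(seed),
            )
            ci[level] = (float(res.confidence_interval.low), float(res.confidence_interval.high))
        else:
            raise ValueError(f"unknown CI method {method!r}")
    return ElevationSummary(
        n=n,
        mean=mean,
        median=float(np.median(x)),
        ci=ci,
        lower_bound_exceeds_1={lvl: ci[lvl][0] > 1.0 for lvl in ci},
    )


@dataclass(frozen=True)
class ComparisonSummary:
    n: int
    n_higher_a: int
    n_higher_b: int
    n_ties: int
    pct_higher_a: float
    median_elevation: float
    mean_elevation: float
    ci: dict[float, tuple[float, float]]
    sign_test: StatTestResult
    wilcoxon: StatTestResult
    wilcoxon_mode: str


def summarize_comparison(
    comparisons: Sequence[GeneComparison],
    alternative: str = "one-sided-a-greater",
    levels: Sequence[float] = (0.99,),
    wilcoxon_mode: str = "signed-rank",
) -> ComparisonSummary:
    """Full per-comparison summary: counts, percentage, elevation stats, tests.

    Exact ties (ratio_a == ratio_b) are excluded from the sign-test counts;
    the percentage is over untied genes.
    """
    if not comparisons:
        raise ValueError("no gene comparisons")
    n_a = sum(c.ratio_a > c.ratio_b for c in comparisons)
    n_b = sum(c.ratio_b > c.ratio_a for c in comparisons)
    n_ties = len(comparisons) - n_a - n_b
    indices = [c.elevation for c in comparisons]
    elev = summarize_elevation(indices, levels=levels)
    return ComparisonSummary(
        n=len(comparisons),
        n_higher_a=n_a,
        n_higher_b=n_b,
        n_ties=n_ties,
        pct_higher_a=pct_higher_a(n_a, n_b),
        median_elevation=elev.median,
        mean_elevation=elev.mean,
        ci=elev.ci,
        sign_test=sign_test(n_a, n_b, alternative=alternative),
        wilcoxon=wilcoxon_chisq(
            [c.ratio_a for c in comparisons],
            [c.ratio_b for c in comparisons],
            mode=wilcoxon_mode,
        ),
        wilcoxon_mode=wilcoxon_mode,
    )


def pct_higher_a(n_higher_a: int, n_higher_b: int) -> float:
    """Percentage of untied genes with the higher D_r/D_c in pair A."""
    total = n_higher_a + n_higher_b
    if total == 0:
        raise ValueError("no untied genes")
    return 100.0 * n_higher_a / total


def summarize_by_category(
    comparisons: Sequence[GeneComparison],
    alternative: str = "one-sided-a-greater",
    levels: Sequence[float] = (0.95, 0.99),
) -> dict[str, ComparisonSummary]:
    """Per-functional-category summaries; multi-label genes count in each of
    their categories, unlabeled genes fall into ``Unclassified``."""
    buckets: dict[str, list[GeneComparison]] = {}
    for c in comparisons:
        labels = c.categories or ("Unclassified",)
        for label in labels:
            buckets.setdefault(label, []).append(c)
    return {
        label: summarize_comparison(members, alternative=alternative, levels=levels)
        for label, members in sorted(buckets.items())
    }


# ---------------------------------------------------------------------------
# Factorial ANOVA


def anova_factorial(
    results: pd.DataFrame,
    response: str = "ratio",
    factors: Sequence[str] = ("freq_table", "kappa", "t", "omega"),
) -> pd.DataFrame:
    """Main-effects ANOVA of a (simulation) results table.

    All factors are treated as categorical; rows with a missing response are
    dropped.  Returns a table with per-factor df, sum of squares, F and p plus
    the residual row.  For unbalanced data a Type-I (sequential)
    decomposition is used and flagged in ``df.attrs['decomposition']``.
    """
    df = results.dropna(subset=[response]).copy()
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor {f!r} not in results")
        df[f] = df[f].astype(str)
    counts = df.groupby(list(factors), observed=True).size()
    balanced = counts.nunique() == 1
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index={f"C({f})": f for f in factors})
    table.attrs["decomposition"] = "Type I"
    table.attrs["balanced"] = bool(balanced)
    return table
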