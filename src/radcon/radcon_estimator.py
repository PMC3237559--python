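"""Counting-based estimation of radical and conservative divergence (D_r, D_c).

The approach follows the pathway-counting family of dN/dS estimators, split by
a physiochemical classification of amino-acid changes and weighted for the
transition/transversion bias:

* Each codon contributes 3 mutational sites, apportioned among synonymous,
  radical-nonsynonymous and conservative-nonsynonymous categories.  Each of
  the 9 single-nucleotide neighbours receives weight ``kappa`` (transition) or
  1 (transversion); neighbours that are stop codons are dropped.
* Differences between two codons are resolved by enumerating all orderings of
  the single-nucleotide steps; orderings passing through a stop codon are
  discarded and the per-category step counts are averaged over the remainder.
* Proportions p_r = N_r/L_r and p_c = N_c/L_c are corrected for multiple hits
  with the Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3), which is undefined
  for p >= 0.75.

Standard errors use the binomial/delta-method reconstruction documented in
``docs/methods.md``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codon_core import (
    NUCLEOTIDES,
    SENSE_CODONS,
    STANDARD_CODE,
    ClassificationScheme,
    CodonAlignment,
    is_transition,
    translate,
)

SYN, RAD, CON = 0, 1, 2


class UncountableCodonPairError(ValueError):
    """All mutational pathways between two codons pass through a stop codon."""


class JukesCantorDomainError(ValueError):
    """Uncorrected divergence >= 0.75; the log correction is undefined."""


def jukes_cantor_correct(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3) for 0 <= p < 0.75."""
    if p < 0:
        raise ValueError(f"negative divergence {p!r}")
    if p >= 0.75:
        raise JukesCantorDomainError(
            f"uncorrected divergence {p} >= 0.75: Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Site counting


@lru_cache(maxsize=None)
def _site_weight_components(
    codon: str, scheme: ClassificationScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of transition/transversion neighbours per category for one codon.

    Returns (ts_counts, tv_counts), each a length-3 vector over
    (synonymous, radical, conservative).  Stop-codon neighbours contribute to
    neither numerator (their weight is simply lost from the site total).
    """
    aa = translate(codon)
    ts = np.zeros(3)
    tv = np.zeros(3)
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STANDARD_CODE.stops:
                continue
            aa2 = translate(mutant)
            if aa2 == aa:
                cat = SYN
            elif scheme.is_radical(aa, aa2):
                cat = RAD
            else:
                cat = CON
            if is_transition(codon[pos], nt):
                ts[cat] += 1
            else:
                tv[cat] += 1
    return ts, tv


def count_codon_sites(
    codon: str, kappa: float, scheme: ClassificationScheme
) -> tuple[float, float, float]:
    """Apportion the 3 sites of a codon to (synonymous, radical, conservative).

    Each single-nucleotide mutation is weighted ``kappa`` (transition) or 1
    (transversion); mutations to stop codons are dropped, so the categories
    sum to ``3 * (weighted non-stop fraction)``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if codon in STANDARD_CODE.stops:
        raise ValueError(f"stop codon {codon!r} has no sites")
    ts, tv = _site_weight_components(codon, scheme)
    sites = (kappa * ts + tv) / (kappa + 2.0)
    return float(sites[SYN]), float(sites[RAD]), float(sites[CON])


# ---------------------------------------------------------------------------
# Difference counting


def _enumerate_pathways(codon_a: str, codon_b: str) -> Iterable[list[tuple[str, str]]]:
    """All orderings of the differing positions, as lists of (from, to) codon steps."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in itertools.permutations(diff):
        cur = codon_a
        steps = []
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        yield steps


@lru_cache(maxsize=None)
def _pair_difference_cached(
    codon_a: str, codon_b: str, scheme: ClassificationScheme
) -> tuple[float, float, float]:
    valid_paths = []
    for steps in _enumerate_pathways(codon_a, codon_b):
        if any(c2 in STANDARD_CODE.stops for _, c2 in steps):
            continue
        counts = np.zeros(3)
        for c1, c2 in steps:
            a1, a2 = translate(c1), translate(c2)
            if a1 == a2:
                counts[SYN] += 1
            elif scheme.is_radical(a1, a2):
                counts[RAD] += 1
            else:
                counts[CON] += 1
        valid_paths.append(counts)
    if not valid_paths:
        raise UncountableCodonPairError(
            f"all pathways between {codon_a} and {codon_b} pass through stop codons"
        )
    mean = np.mean(valid_paths, axis=0)
    return float(mean[SYN]), float(mean[RAD]), float(mean[CON])


def count_pair_differences(
    codon_a: str, codon_b: str, scheme: ClassificationScheme
) -> tuple[float, float, float]:
    """(synonymous, radical, conservative) differences between two sense codons.

    Multi-step pathways are averaged with equal weight over all orderings whose
    intermediates are sense codons; symmetric in its arguments.
    """
    for c in (codon_a, codon_b):
        if c not in set(SENSE_CODONS):
            raise ValueError(f"not a sense codon: {c!r}")
    if codon_a == codon_b:
        return (0.0, 0.0, 0.0)
    return _pair_difference_cached(*sorted((codon_a, codon_b)), scheme)


# ---------------------------------------------------------------------------
# Per-alignment estimation


@dataclass(frozen=True)
class RadConCounts:
    L_r: float
    L_c: float
    L_s: float
    N_r: float
    N_c: float
    N_s: float
    n_codons: int
    n_uncountable: int


@dataclass(frozen=True)
class RadConEstimate:
    counts: RadConCounts
    p_r: float
    p_c: float
    D_r: float | None
    D_c: float | None
    ratio: float | None
    se_Dr: float | None
    se_Dc: float | None
    se_ratio: float | None
    scheme: str
    kappa_used: float
    gene: str = ""


def _divergence_with_se(N: float, L: float) -> tuple[float, float | None, float | None]:
    """p = N/L, its JC correction and delta-method standard error.

    Returns (p, D, se_D); D and se_D are None when p >= 0.75 (uncorrectable).
    """
    p = N / L if L > 0 else 0.0
    if p >= 0.75:
        return p, None, None
    D = jukes_cantor_correct(p)
    var_p = p * (1.0 - p) / L if L > 0 else 0.0
    se_D = math.sqrt(var_p) / (1.0 - 4.0 * p / 3.0)
    return p, D, se_D


def estimate_dr_dc(
    aln: CodonAlignment,
    kappa: float,
    scheme: ClassificationScheme,
    gene: str = "",
) -> RadConEstimate:
    """Estimate D_r, D_c and their ratio for one aligned codon pair.

    Site totals are computed per sequence and averaged over the two sequences;
    differences are summed over countable codon columns.  ``kappa`` is the
    transition/transversion rate ratio used in the site weighting (typically
    taken from the codon-model ML fit for the same pair).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    sites_a = np.zeros(3)
    sites_b = np.zeros(3)
    diffs = np.zeros(3)
    n_codons = 0
    n_uncountable = 0
    for ca, cb in aln.countable_columns():
        try:
            d = count_pair_differences(ca, cb, scheme)
        except UncountableCodonPairError:
            n_uncountable += 1
            continue
        sites_a += count_codon_sites(ca, kappa, scheme)
        sites_b += count_codon_sites(cb, kappa, scheme)
        diffs += d
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no countable codon columns in alignment")
    sites = (sites_a + sites_b) / 2.0
    counts = RadConCounts(
        L_r=float(sites[RAD]),
        L_c=float(sites[CON]),
        L_s=float(sites[SYN]),
        N_r=float(diffs[RAD]),
        N_c=float(diffs[CON]),
        N_s=float(diffs[SYN]),
        n_codons=n_codons,
        n_uncountable=n_uncountable,
    )
    p_r, D_r, se_Dr = _divergence_with_se(counts.N_r, counts.L_r)
    p_c, D_c, se_Dc = _divergence_with_se(counts.N_c, counts.L_c)
    ratio = se_ratio = None
    if D_r is not None and D_c is not None and D_c > 0:
        ratio = D_r / D_c
        if D_r > 0:
            rel2 = (se_Dr / D_r) ** 2 + (se_Dc / D_c) ** 2
            se_ratio = ratio * math.sqrt(rel2)
    return RadConEstimate(
        counts=counts,
        p_r=p_r,
        p_c=p_c,
        D_r=D_r,
        D_c=D_c,
        ratio=ratio,
        se_Dr=se_Dr,
        se_Dc=se_Dc,
        se_ratio=se_ratio,
        scheme=scheme.name,
        kappa_used=kappa,
        gene=gene,
    )


# ---------------------------------------------------------------------------
# High s.e. filter

ZERO_RADICAL = "zero-radical"
ZERO_CONSERVATIVE = "zero-conservative"
SE_OVER_50PCT = "se-over-50pct"
UNCORRECTABLE = "uncorrectable-over-0.75"


@dataclass(frozen=True)
class FilterReport:
    kept: bool
    reasons: tuple[str, ...]


def filter_estimate(est: RadConEstimate, preset: str = "high-se") -> FilterReport:
    """Apply the unreliable-estimate filter to a single gene.

    ``high-se`` drops genes with zero radical or zero conservative differences,
    a D_r/D_c standard error above 50% of the ratio, or an uncorrectable
    (>= 0.75) raw divergence.  ``zero-only`` (the less stringent preset used
    for very close genome pairs) drops only the zero-count rules.
    """
    if preset not in ("high-se", "zero-only"):
        raise ValueError(f"unknown filter preset {preset!r}")
    reasons: list[str] = []
    if est.counts.N_r <= 0:
        reasons.append(ZERO_RADICAL)
    if est.counts.N_c <= 0:
        reasons.append(ZERO_CONSERVATIVE)
    if preset == "high-se":
        if est.p_r >= 0.75 or est.p_c >= 0.75:
            reasons.append(UNCORRECTABLE)
        if est.ratio is not None and est.se_ratio is not None and est.ratio > 0:
            if est.se_ratio / est.ratio > 0.5:
                reasons.append(SE_OVER_50PCT)
    return FilterReport(kept=not reasons, reasons=tuple(reasons))


def apply_high_se_filter(
    estimates: Sequence[RadConEstimate], preset: str = "high-se"
) -> list[tuple[RadConEstimate, FilterReport]]:
    return [(est, filter_estimate(est, preset=preset)) for est in estimates]


def estimates_to_frame(
    pairs: Iterable[tuple[RadConEstimate, FilterReport]]
) -> pd.DataFrame:
    """Tabulate filtered estimates (one row per gene)."""
    rows = []
    for est, rep in pairs:
        rows.append(
            {
                "gene": est.gene,
                "scheme": est.scheme,
                "kappa_used": est.kappa_used,
                "L_r": est.counts.L_r,
                "L_c": est.counts.L_c,
                "N_r": est.counts.N_r,
                "N_c": est.counts.N_c,
                "N_s": est.counts.N_s,
                "p_r": est.p_r,
                "p_c": est.p_c,
                "D_r": est.D_r,
                "D_c": est.D_c,
                "ratio": est.ratio,
                "se_ratio": est.se_ratio,
                "kept": rep.kept,
                "reasons": ";".join(rep.reasons),
            }
        )
    return pd.DataFrame(rows)
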