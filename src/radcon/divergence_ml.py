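"""Pairwise maximum-likelihood divergence under a codon substitution model.

The model is the Goldman–Yang-style 61-state Markov process: off-diagonal
rates q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for codons
differing at one nucleotide, 0 otherwise, with equilibrium frequencies pi
built from position-specific nucleotide frequencies (F3x4) and the matrix
scaled to one expected substitution per codon site per unit time.  For a pair
of sequences the likelihood of a codon column (i, j) is pi_i * P_ij(t), and
(t, kappa, omega) are estimated jointly by numerical optimisation; dN and dS
are then derived from the fitted matrix by splitting the expected substitution
flux into synonymous and nonsynonymous parts and dividing by the
corresponding site fractions (computed at omega = 1, the mutational
opportunity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .codon_core import (
    CODON_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    CodonAlignment,
    CodonFrequencyTable,
    is_transition,
)

N_CODONS = len(SENSE_CODONS)

T_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.01, 100.0)
OMEGA_BOUNDS = (1e-4, 20.0)


def _neighbour_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-nucleotide neighbours, transitions, synonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            single[i, j] = True
            k = diff[0]
            transition[i, j] = is_transition(ci[k], cj[k])
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous

SINGLE_STEP, TRANSITION_STEP, SYNONYMOUS_STEP = _neighbour_masks()


@dataclass(frozen=True)
class CodonRateMatrix:
    """A scaled, reversible codon rate matrix with its stationary distribution."""

    Q: np.ndarray
    pi: np.ndarray
    kappa: float
    omega: float

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via symmetric eigendecomposition (pi may contain zeros)."""
        lam, V, support = _eigendecompose(self.Q, self.pi)
        return _probability_matrix(lam, V, support, self.pi, t)

    def synonymous_flux_fraction(self) -> float:
        """Fraction of the stationary substitution flux that is synonymous."""
        flux = self.pi[:, None] * self.Q
        total = -float(self.pi @ np.diag(self.Q))
        return float(flux[SYNONYMOUS_STEP].sum() / total)


def build_f3x4(aln: CodonAlignment) -> CodonFrequencyTable:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Nucleotide frequencies at each codon position are pooled across both
    sequences (gapped/ambiguous columns excluded), and each sense codon's
    frequency is the product of its three positional frequencies, renormalised
    over the 61 sense codons.
    """
    counts = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for ca, cb in aln.countable_columns():
        for codon in (ca, cb):
            for pos, nt in enumerate(codon):
                counts[pos, nt_index[nt]] += 1
    if counts.sum() == 0:
        raise ValueError("no countable codons for F3x4")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    raw = np.array(
        [
            pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]] * pos_freq[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero F3x4 codon table")
    return CodonFrequencyTable.from_array(raw / total)


def build_rate_matrix(
    kappa: float, omega: float, freqs: CodonFrequencyTable
) -> CodonRateMatrix:
    """GY94 rate matrix scaled to unit mean substitution rate at stationarity."""
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be positive")
    pi = freqs.as_array()
    if pi.sum() <= 0:
        raise ValueError("degenerate frequency table")
    Q = np.where(SINGLE_STEP, np.tile(pi, (N_CODONS, 1)), 0.0)
    Q = np.where(TRANSITION_STEP, Q * kappa, Q)
    Q = np.where(SINGLE_STEP & ~SYNONYMOUS_STEP, Q * omega, Q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return CodonRateMatrix(Q=Q / mean_rate, pi=pi, kappa=kappa, omega=omega)


def _eigendecompose(
    Q: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the pi-symmetrised generator on the support of pi."""
    support = pi > 0
    piS = pi[support]
    QS = Q[np.ix_(support, support)]
    sq = np.sqrt(piS)
    B = (sq[:, None] * QS) / sq[None, :]
    B = (B + B.T) / 2.0  # reversibility makes B symmetric; enforce numerically
    lam, U = np.linalg.eigh(B)
    return lam, U, support


def _probability_matrix(
    lam: np.ndarray, U: np.ndarray, support: np.ndarray, pi: np.ndarray, t: float
) -> np.ndarray:
    piS = pi[support]
    sq = np.sqrt(piS)
    PS = (U * np.exp(lam * t)) @ U.T
    PS = PS / sq[:, None] * sq[None, :]
    P = np.zeros((len(pi), len(pi)))
    idx = np.where(support)[0]
    P[np.ix_(idx, idx)] = np.clip(PS, 0.0, None)
    # rows outside the support are never visited; leave them absorbing
    P[~support, ~support] = 1.0
    return P


@dataclass(frozen=True)
class PairwiseMLEstimate:
    t: float
    kappa: float
    omega: float
    dN: float
    dS: float
    logL: float
    converged: bool
    at_bound: dict[str, bool] = field(default_factory=dict)
    n_codons: int = 0
    reliable: bool = True
    gene: str = ""


def _count_matrix(aln: CodonAlignment) -> tuple[np.ndarray, int]:
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    counts = np.zeros((N_CODONS, N_CODONS))
    n = 0
    for ca, cb in aln.countable_columns():
        counts[idx[ca], idx[cb]] += 1
        n += 1
    return counts, n


def _log_likelihood(
    params: np.ndarray, counts: np.ndarray, pi: np.ndarray, freqs: CodonFrequencyTable
) -> float:
    t, kappa, omega = np.exp(params)
    rm = build_rate_matrix(kappa, omega, freqs)
    P = rm.transition_probabilities(t)
    lik = pi[:, None] * P
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(np.clip(lik[mask], 1e-300, None))))


def fit_pairwise(
    aln: CodonAlignment,
    freqs: CodonFrequencyTable | None = None,
    n_starts: int = 3,
    gene: str = "",
) -> PairwiseMLEstimate:
    """Fit (t, kappa, omega) by ML for one aligned codon pair.

    ``freqs`` defaults to the pair's own F3x4 table.  Optimisation is
    bounded L-BFGS-B on log-transformed parameters from ``n_starts`` dispersed
    starting points; parameter estimates at the box bounds are flagged.
    """
    if freqs is None:
        freqs = build_f3x4(aln)
    pi = freqs.as_array()
    counts, n = _count_matrix(aln)
    if n == 0:
        raise ValueError("no countable codons")

    p_diff = counts[~np.eye(N_CODONS, dtype=bool)].sum() / n
    t0 = min(max(3.0 * p_diff + 0.05, 0.05), 10.0)
    starts = [(t0, 2.0, 0.3), (0.2, 1.0, 1.0), (5.0, 5.0, 0.1)][: max(1, n_starts)]

    log_bounds = [tuple(np.log(b)) for b in (T_BOUNDS, KAPPA_BOUNDS, OMEGA_BOUNDS)]
    best = None
    converged = False
    for start in starts:
        res = minimize(
            lambda p: -_log_likelihood(p, counts, pi, freqs),
            np.log(start),
            method="L-BFGS-B",
            bounds=log_bounds,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    t, kappa, omega = np.exp(best.x)

    rm = build_rate_matrix(kappa, omega, freqs)
    rho_S = rm.synonymous_flux_fraction()
    rm1 = build_rate_matrix(kappa, 1.0, freqs)
    S_frac = rm1.synonymous_flux_fraction()  # synonymous fraction of site opportunity
    dS = t * rho_S / (3.0 * S_frac) if S_frac > 0 else float("nan")
    dN = t * (1.0 - rho_S) / (3.0 * (1.0 - S_frac)) if S_frac < 1 else float("nan")

    def near(value: float, bounds: tuple[float, float]) -> bool:
        lo, hi = bounds
        return value <= lo * (1 + 1e-3) or value >= hi * (1 - 1e-3)

    return PairwiseMLEstimate(
        t=float(t),
        kappa=float(kappa),
        omega=float(omega),
        dN=float(dN),
        dS=float(dS),
        logL=-float(best.fun),
        converged=converged,
        at_bound={
            "t": near(t, T_BOUNDS),
            "kappa": near(kappa, KAPPA_BOUNDS),
            "omega": near(omega, OMEGA_BOUNDS),
        },
        n_codons=n,
        reliable=n >= 10,
        gene=gene,
    )


def fits_to_frame(fits: Sequence[PairwiseMLEstimate]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "t": [f.t for f in fits],
            "kappa": [f.kappa for f in fits],
            "omega": [f.omega for f in fits],
            "dN": [f.dN for f in fits],
            "dS": [f.dS for f in fits],
            "logL": [f.logL for f in fits],
            "converged": [f.converged for f in fits],
            "reliable": [f.reliable for f in fits],
        }
    )
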