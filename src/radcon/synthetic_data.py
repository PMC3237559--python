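"""Synthetic inputs: GC-controlled codon tables, two-omega gene simulations
with known ground truth, and multi-gene two-genome-pair study fixtures.

The *two-omega* generator extends the codon model with classification-aware
selection: nonsynonymous rates are multiplied by ``omega_r`` for radical and
``omega_c`` for conservative changes, so the true constraint ratio
``omega_r/omega_c`` is known and the response of estimated D_r/D_c to
differential constraint on radical changes becomes a testable property.
Setting ``omega_r == omega_c`` recovers the classification-blind model
exactly.

Study fixtures emulate a two-genome-pair, multi-ortholog comparison: each
gene is simulated for genome pair A and genome pair B from templates with
gene-level lognormal variation in t and omega, optional functional-category
labels are assigned, and everything needed by the downstream pipeline
(aligned FASTA per gene, ground truth, categories, manifest) is written out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codon_core import (
    NUCLEOTIDES,
    SENSE_CODONS,
    ClassificationScheme,
    CodonAlignment,
    CodonFrequencyTable,
    read_fasta_pair,
    write_fasta_pair,
)
from .divergence_ml import (
    SINGLE_STEP,
    SYNONYMOUS_STEP,
    TRANSITION_STEP,
    CodonRateMatrix,
    fit_pairwise,
)
from .codon_simulator import SimulationSpec, simulate_pair
from .radcon_estimator import estimate_dr_dc, filter_estimate

N_CODONS = len(SENSE_CODONS)


# ---------------------------------------------------------------------------
# Frequency tables of controlled GC


def _table_from_position_freqs(pos_freq: np.ndarray) -> CodonFrequencyTable:
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    raw = np.array(
        [
            pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]] * pos_freq[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError("infeasible position frequencies: zero sense-codon mass")
    return CodonFrequencyTable.from_array(raw / total)


def make_frequency_table(
    gc_target: float,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
    tol: float = 0.02,
) -> CodonFrequencyTable:
    """A sense-codon frequency table whose GC content matches ``gc_target``.

    Position-specific nucleotide frequencies are parametrised by a per-position
    GC mass ``g`` (A=T, C=G by default; ``jitter`` > 0 draws lognormal
    within-pair perturbations from ``rng``), and ``g`` is solved by bisection
    so that the renormalised sense-codon table — stops excluded, which shifts
    composition slightly — hits the target within ``tol``.
    """
    if not 0.1 < gc_target < 0.9:
        raise ValueError("gc_target must be in (0.1, 0.9)")
    if jitter > 0 and rng is None:
        rng = np.random.default_rng()
    # within-class weights per position: [A, C, G, T]
    weights = np.ones((3, 4))
    if jitter > 0:
        weights = np.exp(rng.normal(0.0, jitter, size=(3, 4)))

    def table_at(g: float) -> CodonFrequencyTable:
        pos = np.empty((3, 4))
        for p in range(3):
            at = weights[p, [0, 3]] / weights[p, [0, 3]].sum() * (1.0 - g)
            gc = weights[p, [1, 2]] / weights[p, [1, 2]].sum() * g
            pos[p] = [at[0], gc[0], gc[1], at[1]]
        return _table_from_position_freqs(pos)

    lo, hi = 1e-4, 1.0 - 1e-4
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if table_at(mid).gc_content() < gc_target:
            lo = mid
        else:
            hi = mid
    table = table_at((lo + hi) / 2.0)
    if abs(table.gc_content() - gc_target) > tol:
        raise ValueError(
            f"could not reach GC {gc_target:.3f}: achieved {table.gc_content():.3f}"
        )
    return table


def default_grid_tables() -> dict[str, CodonFrequencyTable]:
    """Bundled synthetic stand-ins for the three genome codon tables of the
    factorial experiment, matched on GC content (26%, 27%, 51%)."""
    return {
        "at26": make_frequency_table(0.26),
        "at27": make_frequency_table(0.27),
        "gc51": make_frequency_table(0.51),
    }


# ---------------------------------------------------------------------------
# Two-omega model


@dataclass(frozen=True)
class TwoOmegaSpec:
    freqs: CodonFrequencyTable
    kappa: float
    omega_r: float
    omega_c: float
    scheme: ClassificationScheme
    t: float
    n_codons: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.omega_r <= 0 or self.omega_c <= 0:
            raise ValueError("omega_r and omega_c must be positive")
        if self.kappa <= 0 or self.t < 0 or self.n_codons < 1:
            raise ValueError("invalid spec")

    @property
    def constraint_ratio(self) -> float:
        return self.omega_r / self.omega_c


def _radical_mask(scheme: ClassificationScheme) -> np.ndarray:
    from .codon_core import CODON_AA

    rad = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i in range(N_CODONS):
        for j in range(N_CODONS):
            if SINGLE_STEP[i, j] and not SYNONYMOUS_STEP[i, j]:
                rad[i, j] = scheme.is_radical(CODON_AA[i], CODON_AA[j])
    return rad


def build_two_omega_matrix(spec: TwoOmegaSpec) -> CodonRateMatrix:
    """GY94-style matrix with separate radical/conservative omega multipliers.

    Reversibility is preserved because the radical/conservative label is
    symmetric in the two codons.  ``omega_r == omega_c`` reproduces the
    single-omega matrix exactly.
    """
    pi = spec.freqs.as_array()
    rad = _radical_mask(spec.scheme)
    Q = np.where(SINGLE_STEP, np.tile(pi, (N_CODONS, 1)), 0.0)
    Q = np.where(TRANSITION_STEP, Q * spec.kappa, Q)
    nonsyn = SINGLE_STEP & ~SYNONYMOUS_STEP
    Q = np.where(nonsyn & rad, Q * spec.omega_r, Q)
    Q = np.where(nonsyn & ~rad, Q * spec.omega_c, Q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    return CodonRateMatrix(Q=Q / mean_rate, pi=pi, kappa=spec.kappa, omega=np.nan)


def simulate_two_omega_gene(
    spec: TwoOmegaSpec,
    rng: np.random.Generator | None = None,
    id_a: str = "a",
    id_b: str = "b",
) -> tuple[CodonAlignment, dict]:
    """Simulate one gene pair under the two-omega model with its ground truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rm = build_two_omega_matrix(spec)
    sim_spec = SimulationSpec(
        freqs=spec.freqs, kappa=spec.kappa, omega=1.0, t=spec.t,
        n_codons=spec.n_codons, seed=spec.seed,
    )
    aln = simulate_pair(sim_spec, rng=rng, rate_matrix=rm, id_a=id_a, id_b=id_b)
    truth = {
        "omega_r": spec.omega_r,
        "omega_c": spec.omega_c,
        "constraint_ratio": spec.constraint_ratio,
        "kappa": spec.kappa,
        "t": spec.t,
        "n_codons": spec.n_codons,
        "seed": spec.seed,
        "scheme": spec.scheme.name,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Study fixtures


@dataclass(frozen=True)
class StudyFixtureSpec:
    n_genes: int
    template_a: TwoOmegaSpec
    template_b: TwoOmegaSpec
    t_sigma: float = 0.3  # lognormal sd of gene-level t around the template
    omega_sigma: float = 0.2  # lognormal sd applied jointly to omega_r, omega_c
    category_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Cell processes": 0.09,
            "Cell structure": 0.18,
            "Information transfer": 0.30,
            "Metabolism": 0.28,
            "Regulation": 0.05,
            "Transport": 0.06,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def generate_study_fixture(spec: StudyFixtureSpec, out_dir: str | Path | None = None) -> dict:
    """Generate a multi-gene, two-genome-pair dataset with known ground truth.

    Gene-level t and omega multipliers are drawn once per gene from lognormal
    distributions and shared between the two genome pairs (orthologs share a
    gene-specific rate/constraint profile), so pair-level differences come
    only from the templates.  Returns alignments keyed by gene id and, when
    ``out_dir`` is given, writes FASTA per gene per pair, ground_truth.tsv,
    categories.tsv and a manifest recording every seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    alignments: dict[str, dict[str, CodonAlignment]] = {}
    truth_rows = []
    categories: dict[str, tuple[str, ...]] = {}
    labels = list(spec.category_probs)
    probs = list(spec.category_probs.values())
    for gene in genes:
        t_mult = float(np.exp(rng.normal(0.0, spec.t_sigma)))
        om_mult = float(np.exp(rng.normal(0.0, spec.omega_sigma)))
        gene_alns = {}
        for pair_name, template in (("A", spec.template_a), ("B", spec.template_b)):
            seed = int(rng.integers(0, 2**31 - 1))
            gene_spec = replace(
                template,
                t=template.t * t_mult,
                omega_r=template.omega_r * om_mult,
                omega_c=template.omega_c * om_mult,
                seed=seed,
            )
            aln, truth = simulate_two_omega_gene(
                gene_spec, id_a=f"{gene}_{pair_name}1", id_b=f"{gene}_{pair_name}2"
            )
            gene_alns[pair_name] = aln
            truth_rows.append({"gene": gene, "pair": pair_name, **truth})
        alignments[gene] = gene_alns
        assigned = tuple(l for l, p in zip(labels, probs) if rng.random() < p)
        categories[gene] = assigned

    result = {
        "alignments": alignments,
        "ground_truth": pd.DataFrame(truth_rows),
        "categories": categories,
        "seed": spec.seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        for pair_name in ("A", "B"):
            (out / f"pair_{pair_name}").mkdir(parents=True, exist_ok=True)
        for gene, gene_alns in alignments.items():
            for pair_name, aln in gene_alns.items():
                write_fasta_pair(aln, out / f"pair_{pair_name}" / f"{gene}.fasta")
        result["ground_truth"].to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        with open(out / "categories.tsv", "w") as fh:
            fh.write("gene\tcategories\n")
            for gene in genes:
                fh.write(f"{gene}\t{';'.join(categories[gene])}\n")
        manifest = {
            "n_genes": spec.n_genes,
            "seed": spec.seed,
            "t_sigma": spec.t_sigma,
            "omega_sigma": spec.omega_sigma,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def load_study_fixture(fixture_dir: str | Path) -> dict:
    """Read back a written study fixture (alignments, ground truth, categories)."""
    out = Path(fixture_dir)
    alignments: dict[str, dict[str, CodonAlignment]] = {}
    for pair_name in ("A", "B"):
        for path in sorted((out / f"pair_{pair_name}").glob("*.fasta")):
            alignments.setdefault(path.stem, {})[pair_name] = read_fasta_pair(path)
    truth = pd.read_csv(out / "ground_truth.tsv", sep="\t")
    cats = {}
    for line in (out / "categories.tsv").read_text().splitlines()[1:]:
        gene, labels = (line.split("\t") + [""])[:2]
        cats[gene] = tuple(l for l in labels.split(";") if l)
    return {"alignments": alignments, "ground_truth": truth, "categories": cats}


def estimate_fixture_ratios(
    fixture: dict,
    scheme: ClassificationScheme,
    kappa: str | float = "fit",
    filter_preset: str = "high-se",
) -> dict[str, dict[str, float]]:
    """Run fit -> estimate -> filter over a fixture, per genome pair.

    ``kappa`` is ``"fit"`` (per-pair ML estimate, mirroring the empirical
    pipeline), ``"true"`` (the generating value from the ground truth), or a
    number.  Returns ``{"A": {gene: ratio}, "B": {...}}`` with filtered-out or
    undefined genes omitted.
    """
    truth = fixture["ground_truth"].set_index(["gene", "pair"])
    out: dict[str, dict[str, float]] = {"A": {}, "B": {}}
    for gene, gene_alns in fixture["alignments"].items():
        for pair_name, aln in gene_alns.items():
            if kappa == "fit":
                k = fit_pairwise(aln, n_starts=1).kappa
            elif kappa == "true":
                k = float(truth.loc[(gene, pair_name), "kappa"])
            else:
                k = float(kappa)
            est = estimate_dr_dc(aln, kappa=k, scheme=scheme, gene=gene)
            if filter_estimate(est, preset=filter_preset).kept and est.ratio is not None:
                out[pair_name][gene] = est.ratio
    return out
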