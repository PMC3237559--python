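# Methods

## Background and scope

`radcon` measures selective constraint on protein-coding genes through the
ratio of per-site rates of *radical* to *conservative* nonsynonymous
substitution, D_r/D_c.  A replacement is radical when it crosses groups of a
physiochemical classification of the 20 amino acids (by charge, polarity, or
polarity-and-volume), conservative when it stays within a group.  Like
dN/dS, D_r/D_c is expected to rise when purifying selection is weak — for
instance in obligate intracellular endosymbionts with tiny effective
population sizes — but unlike dN/dS it remains usable at divergences deep
enough to saturate synonymous sites.

The package covers the full analysis cycle: estimation from codon-aligned
sequence pairs, pairwise codon-model ML fits (supplying the
transition/transversion ratio the estimator needs), simulation-based bias
auditing, paired-gene comparative statistics, and a synthetic-data module
that generates every input with known ground truth.

## The counting estimator

For one aligned pair of in-frame coding sequences and a classification
scheme, each codon contributes three mutational sites apportioned among
synonymous, radical and conservative categories.  Each of the nine
single-nucleotide neighbours receives weight `kappa` if the change is a
transition and 1 if a transversion; neighbours that are stop codons are
dropped, so a codon's categories sum to `3 × (weighted non-stop fraction)`.
Site totals L_r and L_c are computed per sequence and averaged over the two
sequences (the standard convention in this estimator family; the choice
matters little because the two sequences share a composition at
stationarity).

Differences between two codons are resolved by enumerating all orderings of
the single-nucleotide steps.  Each step is classified from its endpoint
amino acids; orderings passing through a stop codon are discarded; the
per-category counts are averaged with equal weight over the remaining
orderings.  A codon column whose orderings are all discarded is excluded
from both numerators and denominators and counted in a diagnostics field
(`n_uncountable`).  Columns with gaps or non-ACGT characters in either
sequence are likewise excluded (pairwise deletion).

Proportions p_r = N_r/L_r and p_c = N_c/L_c are corrected independently for
multiple hits with the Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3), which
is undefined for p ≥ 0.75; such genes are flagged uncorrectable.

Standard errors use a binomial/delta-method reconstruction:
Var(p) = p(1−p)/L, Var(D) = Var(p)/(1 − 4p/3)², and for the ratio
(se_ratio/ratio)² = (se_Dr/D_r)² + (se_Dc/D_c)².  The original program this
estimator family descends from does not publish its variance formulas; this
is the standard reconstruction and should be read as such.

### The unreliable-estimate filter

`filter_estimate(..., preset="high-se")` drops genes with zero radical or
zero conservative differences, a ratio standard error above 50% of the
ratio, or an uncorrectable (≥ 0.75) raw divergence.  The `zero-only` preset
keeps high-s.e. genes and drops only the zero-count rules; it exists for
very close genome pairs where most genes have few amino-acid changes and
the stringent filter would discard the bulk of the data.

## Classification schemes

Three schemes ship as editable text files (`GROUPNAME: LETTERS`, one group
per line): `charge` ({R,H,K} / {D,E} / remainder), `polarity`
(polar {R,N,D,C,Q,E,G,H,K,S,T,Y} / nonpolar {A,I,L,M,F,P,W,V}) and `MY`
(six polarity-and-volume groups {C}, {A,G,P,S,T}, {N,D,Q,E}, {R,H,K},
{I,L,M,V}, {F,W,Y}).  A fourth scheme sometimes used in this literature
(HAN) is defined only in supplementary material we could not bundle;
requesting it raises a clear diagnostic, and any user-transcribed partition
can be loaded from a file.  Schemes are validated as exhaustive, disjoint
partitions of the 20 amino acids at load time.

## Pairwise ML divergence

The codon model is the 61-state Goldman–Yang process:
q_ij = π_j · kappa^[transition] · omega^[nonsynonymous] for single-nucleotide
changes, with F3x4 equilibrium frequencies (products of position-specific
nucleotide frequencies pooled over both sequences, renormalised over sense
codons) and the matrix scaled to one expected substitution per codon site
per unit time.  The column likelihood is π_i·P_ij(t) with P(t) computed by
symmetric eigendecomposition on the support of π (reversibility makes
D^{1/2} Q D^{−1/2} symmetric; codons with zero F3x4 frequency are never
observed and are left out of the decomposition).

(t, kappa, omega) are maximised by bounded L-BFGS-B on log-parameters with
t ∈ [1e−6, 50], kappa ∈ [0.01, 100], omega ∈ [1e−4, 20], from up to three
dispersed starts (the first start sets t from the observed nucleotide
p-distance).  Estimates within 0.1% of a box bound are flagged `at_bound`.
The t cap of 50 is deliberate: for saturated pairs the fitted distance
should pile up at the cap rather than wander, and with synonymous sites
saturated but nonsynonymous sites still informative (small omega) the
median reported t over replicate deep pairs is exactly 50 — the behaviour
real deep genome pairs show.  When *all* signal is saturated the likelihood
becomes flat in t and the finite-sample maximum can be interior; this is a
property of the data, not the optimiser.

dN and dS are derived from the MLE by flux decomposition: with the fitted
matrix scaled to unit mean rate, ρ_S is the synonymous fraction of
stationary substitution flux, the synonymous site fraction S/(S+N) is the
same quantity computed at omega = 1 (mutational opportunity), and
dS = t·ρ_S/(3·S/(S+N)), dN analogously.  This follows the ML counting
convention; exact numeric parity with other implementations' dS is not
promised (their site definitions differ subtly across versions), only
convention-consistency.

No among-site rate variation is modelled.

## Simulation

Pairs are generated on a two-branch star: a root sequence drawn from the
model's stationary codon frequencies and two descendants evolved
independently for t/2 each, so the expected pairwise distance is t.  Sites
evolve by exact transition-probability sampling (matrix exponential at
t/2) — exact at any divergence, no event-count truncation, no indels, and
never a stop codon.  Every pair records its seed; identical specs reproduce
identical alignments.

Because the generating model never consults a classification scheme, the
true D_r/D_c of simulated data is 1, and the estimator's deviation from 1
measures its bias.  `run_grid` drives the full factorial
(3 codon tables × dN/dS ∈ {0.3, 0.6} × t ∈ {0.5, 1, 4} ×
kappa ∈ {1, 2, 5, 10} = 72 cells; 500 pairs of 1,200 nt per cell = 36,000
pairs at full scale), analysing each pair exactly as empirical data: ML fit
first, then the counting estimator with the pair's own fitted kappa.
Reduced per-cell counts are used in the test suite and acceptance script;
the driver is identical at any scale.

### What the synthetic codon tables do and do not emulate

`make_frequency_table(gc_target)` builds position-wise nucleotide
frequencies (A=T and C=G within a position by default, optional seeded
jitter) and solves the per-position GC mass by bisection so the
renormalised sense-codon table hits the target GC within 0.02.  These
tables control GC exactly but are *products* of positional frequencies;
real genome codon-usage tables additionally encode a proteome's amino-acid
composition and its relative synonymous codon usage, which a product table
cannot represent.

This matters for the bias audit.  The estimator's composition bias is
governed by the gap between two ratios: the radical/conservative split of
the *realized substitution flux* (which weights target codons by their
frequency, q_ij ∝ π_j) and the split of the *mutational-opportunity site
counts* (which weight all targets equally).  That gap depends on the
detailed 61-dimensional structure of the table, not on GC alone.  Under
AT-rich product tables the flux is radical-enriched relative to opportunity
and the estimated D_r/D_c is *inflated* (≈ 1.12 at 26% GC, kappa 2, t 1)
relative to balanced tables (≈ 1.01); under tables that hold a typical
proteome amino-acid composition fixed while skewing synonymous usage
AT-ward, the bias flips to deflation (≈ 0.92).  Consequently, passing the
null and monotonicity suites here demonstrates estimator correctness and
sensitivity, but the direction of the composition bias measured on
synthetic product tables should not be extrapolated to real genome tables —
users replicating a genome-level bias audit should supply codon tables
computed from the genomes themselves (`CodonFrequencyTable.from_tsv`), for
which the grid driver has first-class support.  The kappa dependence of the
bias (shrinking toward deflation as kappa grows) is robust across table
families.

## Two-omega ground truth and study fixtures

To make "D_r/D_c responds to differential constraint on radical changes" a
testable property, the two-omega generator multiplies nonsynonymous rates
by omega_r (radical) or omega_c (conservative) according to a scheme;
omega_r = omega_c reduces exactly to the blind model, and the true
constraint ratio omega_r/omega_c is the recovery target.  Median estimated
D_r/D_c is strictly increasing in omega_r/omega_c (verified over
{0.25, 0.5, 1.0}).

Study fixtures emulate a multi-ortholog, two-genome-pair comparison: per
gene, a distance multiplier (lognormal, sigma 0.3) and a constraint
multiplier applied jointly to omega_r and omega_c (lognormal, sigma 0.2)
are drawn once and shared between the pairs, so orthologs keep a
gene-specific rate/constraint profile while pair-level differences come
only from the templates.  Defaults (kappa 2, omega_c 0.6, t 1, 256 genes,
300 codons) echo the divergence levels and gene counts of real genome-pair
comparisons at this depth.  Functional-category labels are assigned
independently with fixed probabilities purely to exercise multi-label
bookkeeping; they carry no biology.  Fixtures do not emulate real gene
content, real category assignments, alignment error, or indels — so
passing fixture tests shows pipeline correctness and statistical power
under the model, not robustness to alignment artefacts.

## Comparative statistics

The per-gene *elevation index* is (D_r/D_c in pair A)/(D_r/D_c in pair B),
always computed gene by gene before any summary (the median of per-gene
indices is not the ratio of medians).  Genes with an undefined or zero
denominator are excluded with a recorded reason.

* **Sign test** — exact binomial at p = ½ on the untied higher-in-A vs
  higher-in-B counts; exact ties are excluded.  One-sided and exact
  two-sided (doubled smaller tail, capped at 1) variants are provided, plus
  a `two-sided-normal` variant (z = (a − n/2)/(√n/2), no continuity
  correction) matching what some statistics packages print for two-way sign
  tests.
* **Wilcoxon with chi-square approximation** — by default the paired
  signed-rank statistic (zero differences dropped, midranks, tie-corrected
  variance) referred to a 1-df chi-square as (W − E[W])²/Var[W]; a
  two-group rank-sum mode is available, and the variant used is recorded in
  the result's method label.  The paired default reflects that per-gene
  ratios from two genome pairs over shared orthologs are paired data.
* **Confidence intervals** of the mean elevation: normal-theory t-intervals
  by default (the CI method behind published tables of this kind is rarely
  stated); a seeded BCa bootstrap (10,000 resamples) is available.
* **Spearman** associations (midrank ties) for dN-vs-D_r/D_c and
  sequence-feature screens.
* **Factorial ANOVA** — main-effects OLS on categorical factors
  (statsmodels), per-factor df = levels − 1; balanced designs give the
  usual orthogonal decomposition, unbalanced input falls back to Type-I
  sequential SS and is flagged in the table's metadata.
* **Per-category summaries** duplicate multi-label genes into each of their
  categories; unlabeled genes report as `Unclassified`.

No multiple-testing correction is applied; per-comparison p-values are
reported raw.

## Numerical and degenerate-input choices

* Transition-probability rows are clipped at 0 and renormalised before
  sampling (guards round-off at large t).
* Likelihood terms are floored at 1e−300 before logging.
* `count_pair_differences` is cached over the 61×61 codon pairs per scheme;
  site-weight components are cached per codon and scheme, making the
  estimator linear-time in alignment length with tiny constants.
* Identical sequences: D_r = D_c = 0, ratio undefined (None), never an
  exception; the ML fit returns t at its lower bound with dN = dS ≈ 0.
* Empty alignments (no countable columns) raise.
* All randomness flows through `numpy.random.Generator`; every simulated
  artefact records the seed that produced it.

## Problem sizes used by the checks

The bundled checks use 500 pairs × 400 codons for the estimator null,
200 + 200 pairs for the composition-bias experiment, 10 pairs/cell × 72
cells for the grid driver (3/cell in the acceptance script), 10,000 codons
for single-fit parameter recovery, and 256-gene fixtures for the
comparative pipeline — sizes chosen so each property is measured with
comfortable Monte-Carlo margin.

## Known limitations

* No among-site rate or omega variation; no indel process.
* dN/dS derivation follows the ML counting convention but is not
  bit-compatible with any specific external implementation.
* The composition-bias audit on bundled synthetic tables characterises the
  estimator on product-form tables only (see above); genome-level claims
  need genome-derived tables.
* The ratio's standard error assumes independence of D_r and D_c, which is
  approximate since both share the alignment.
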