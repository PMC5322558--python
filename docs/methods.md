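# Methods

This note records the models implemented in `ucekit`, the defaults and why
they were chosen, the numerical choices that matter, and what the
synthetic-data tests do and do not demonstrate.

## Element scan

A column of a MAF block is *perfectly conserved* when every row of the
block shows the same unambiguous base: any gap, any `N` or ambiguity code,
or any mismatch breaks a run. Soft-masked (lowercase) bases are uppercased
before comparison, so masking alone never breaks a run. Maximal conserved
runs of at least `min_len` columns (default 80 bp) become elements, named
`<chrom>.<k>` by ascending start within each chromosome. Coordinates are
0-based half-open on the reference row. Two deliberate simplifications:

- Runs are evaluated **within blocks only**. Real multiz blocks break at
  alignment discontinuities, so stitching reference-contiguous runs across
  blocks would assert conservation the alignment does not display; the
  synthetic generator consequently refuses (by default) to plant elements
  straddling a block boundary.
- When a `required_species` set is given, a column only counts if the
  block contains every one of them — the strict reading of "perfectly
  conserved across all species". Columns of blocks missing a required
  species break runs rather than being marginalized.

## Background phylogenetic model and conservation tests

The substitution model is HKY85 (JC69 available for testing): rate matrix
with transition/transversion ratio κ and equilibrium frequencies π,
normalized to one expected substitution per site per unit branch length.
Fitting maximizes the sum of per-column log-likelihoods (Felsenstein
pruning, missing leaves marginalized) over a **single global branch
scale**, κ, and π (softmax-parameterized, initialized at observed base
frequencies) with L-BFGS-B on log-transformed parameters plus one random
restart; per-branch lengths are taken as relative values from the input
tree. This is a deliberate simplification versus a general reversible
model with free branch lengths: five free parameters keep the optimization
robust, and conservation testing is driven by the total tree length scale
rather than fine branch geometry. Identical column patterns are collapsed
with counts before optimization.

"No substitutions" is operationalized two ways:

- `q_identity`: the probability all leaves show the same base (pruning
  with point-mass leaf vectors). The reported element p-value is
  `q_identity ** L`, because leaf identity is the observable the scan
  conditions on.
- `q_zero_event`: the probability of literally zero substitution events,
  Σ_b π_b exp(Q_bb·T_total). Parallel and reverting substitutions can
  restore identity, so `q_zero_event ≤ q_identity` always.

The deceleration LRT scales all branches by λ ∈ [1e-6, 1] under the
alternative; the statistic 2ΔlnL is referred to the 50:50 mixture of χ²₀
and χ²₁ appropriate for a one-sided boundary test. Under the null roughly
half the fits sit at λ̂ = 1 with p = 1, so null p-values are
*stochastically larger* than uniform (conservative) rather than uniform —
the test suite checks exactly that property. Columns are treated as
independent (no rate autocorrelation).

## PRF selection inference

Site classes contribute derived-allele counts i at segregating sites
(1 ≤ i ≤ n−1) with possibly varying sample size n per site. Conditioning
on segregation cancels θ, so fixed differences and monomorphic sites are
not modeled. The per-class distribution of γ = 2Ns for new mutations is
Normal(μ_c, σ²_c) — the hierarchical summaries reported (mean, variance)
determine only the first two moments, and the Normal family keeps the
marginal likelihood a one-dimensional smooth integral.

Numerics: the x-integral of the PRF sampling probability uses 50-point
Gauss–Legendre on (0,1) (the integrand's endpoint singularities are
removable for segregating counts; for neutral γ the integrand is a
polynomial of degree n−1, exact for n ≤ 50). The γ-integral uses 32-point
Gauss–Hermite; between orders 16 and 32 the log-likelihood moves by less
than 1e-6 in the strong-selection and moderate-spread regimes the model
targets, and by ~1e-4 for wide mid-range distributions (σ² ≈ 4 at
μ ≈ −8). Probabilities are normalized by the explicit sum over
i = 1..n−1, so spectra sum to 1 to machine precision. The density ratio is
evaluated in a form stable to |γ| = 350; beyond that an explicit overflow
guard raises.

Ascertainment: elements discovered by zero interspecific divergence are
enriched for strongly negative γ. The correction multiplies the Normal
prior over γ by exp(−D·v(γ)) and renormalizes, where
v(γ) = 2γ/(1−e^{−2γ}) is the fixation rate relative to neutral and D is
the expected number of neutral substitutions over the ascertainment
divergence. This is a **reconstruction** of the published correction (an
exponential zero-fixation weight), not a transcription of it; it is off by
default (D = 0 reproduces the unweighted likelihood exactly) and
switchable per class.

Sampling: per class, Metropolis–Hastings on (μ, log σ) with two kernels
per iteration — a joint move shaped by the Cholesky factor of the
empirical burn-in covariance, and a log σ-only move with its own scale
(the spread is weakly identified in weak-selection classes, leaving a flat
direction a joint random walk traverses slowly). Both scales adapt every
50 iterations during burn-in toward ~30% acceptance and are frozen for the
retained half, preserving detailed balance where samples are kept. Priors
are weakly informative: μ ~ N(0, 100²), log σ ~ N(0, 2²). Defaults follow
the reference protocol: nine chains from overdispersed starts
(μ₀ ~ N(0, 8²), log σ₀ ~ N(0, 0.7²)), 1e5 iterations sampled every ten,
first half discarded as burn-in. Convergence uses the Brooks–Gelman
multivariate PSRF, R̂ = (n−1)/n + (m+1)/m·λ₁ with λ₁ the top eigenvalue
of W⁻¹B/n. Summaries per class: pooled posterior mean, the retained
sample with highest unnormalized log posterior (MAP), and the equal-tailed
2.5/97.5 percentile interval.

## RNA structure scoring

The built-in folder is a Nussinov-style dynamic program over nested
structures with nearest-neighbor stacking bonuses: pair energies GC −3,
AU −2, GU −1 (model units), an extra −1 when a pair stacks directly on
another, hairpin loops of at least three unpaired bases, lonely pairs
permitted, no pseudoknots. It is **not** a Turner-parameter thermodynamic
model; absolute free energies require the pluggable external backend
(`ViennaFolder`, a subprocess wrapper around RNAfold) — the built-in
model's purpose is a fast, exactly testable optimum (it equals exhaustive
enumeration on every random sequence up to length 18 in the tests). T and
U are equivalent on input.

Significance uses exact dinucleotide-preserving randomization
(Altschul–Erickson: random last-exit arborescence into the terminal
vertex, shuffled edge pools, Eulerian walk), which preserves the
dinucleotide count matrix, mononucleotide counts, and both endpoints
exactly. z = (MFE_obs − mean)/sd over the shuffle set (sample sd, n−1);
100 shuffles by default. A degenerate null (sd = 0, e.g. homopolymers) is
reported as *undefined*, never as 0. The length–z relationship uses
Pearson's r with the two-sided t transform on n−2 df, excluding (and
counting) undefined records.

## Composition and annotation

Core-vs-flank A+T compares the centered 60 bp core window of each element
with the two immediately adjacent 60 bp flanks pooled; N bases are
excluded from numerator and denominator, and the measure is
strand-symmetric. The 60 bp composition windows are independent of the
1 kb flanks used to define the "flanking" selection class — two separate
parameters. The Wilcoxon rank-sum test reports the U statistic of the
first sample (the value R prints as W): exact by enumeration when
min(n,m) ≤ 8 without ties, else the normal approximation with midrank tie
correction and continuity correction.

Annotation classification assigns every element base exactly one category
with precedence **CDS > UTR > intron > RNA gene > none**, resolving
multi-annotated bases (e.g. CDS in one isoform, intron in another) the
same way; per-element fractions and the pooled per-base-pair fractions
sum to 1 exactly. The genic report lists one row per element × gene whose
CDS it overlaps, with the CDS-intersected sub-interval. The packaged
21-row genic-element table is a report-format fixture: its row count (21),
distinct loci (16, counted by gene symbol), maximum span (192 bp), and
locus multiplicities (para ×5, slo ×2) are reconstruction targets, but the
table is not a scan ground truth (some printed sub-intervals are shorter
than the scan cutoff).

## Synthetic data: what it emulates, and what it does not

- `simulate_alignment` draws a root sequence from π and evolves each site
  independently down the tree; planted intervals scale branch lengths by
  λ (λ = 0 copies the root base to every leaf). The default tree has 12
  Drosophila-assembly leaves with total length ~3.2 substitutions/site
  and fly-like AT-rich equilibrium frequencies. No indels, no rate
  autocorrelation, no alignment error — so scan recovery on synthetic
  data shows correctness of the run-extraction logic, not robustness to
  misalignment.
- `simulate_sfs` draws γ ~ Normal(μ_c, σ²_c) per site, optionally
  accept/rejects by the ascertainment weight, and samples i by inverse
  CDF of the PRF distribution. Polarization is assumed perfect; real
  derived-allele calling error and demography (e.g. bottlenecks, which
  are known to qualitatively shrink |2Ns| estimates) are not emulated,
  so parameter-recovery tests validate the estimator under its own model
  only.
- `random_seq_with_dinucleotides` and `toy_annotation_generator` provide
  exactly controlled nulls for the RNA and annotation stages.

All generators are bit-reproducible under a fixed seed.

## Problem sizes used in tests and the acceptance script

Tests run the full protocol at reduced scale, chosen once: MCMC recovery
uses 3 chains × 20,000 iterations (thin 10) on two classes of 1,000 SNPs
at n = 130 (means −15 and −2, variances 4 and 1), ten seeded replicates;
scan recovery uses 100 seeded 50 kb alignments with five planted elements
of 80–192 bp. For the scan-recovery check the generator runs in a
deep-divergence regime (default tree scaled ×3, total ~9.5
substitutions/site): exact interval recovery requires the columns
bordering each planted element to be non-identical across all 12 leaves,
and the per-column identity probability must therefore be ≲1e-3 for
boundary extensions to be negligible across 100 runs — at the realistic
default depth (q ≈ 0.05) roughly 40% of runs would legitimately report an
element one column wider than planted. This is a property of exact-match
scoring, not of the scan. The RNA null calibration uses 200 sequences of
length 40 with 40 shuffles each. `scripts/acceptance.py` repeats these
computations (50 scan runs, 3 MCMC replicates) from scratch under a
user-supplied seed.

## Known limitations

- One global rate scale per model; no Γ rate variation, no general
  reversible exchangeabilities. Heterochromatin/euchromatin contrasts are
  handled by fitting twice on different column masks.
- The ascertainment weight is a documented reconstruction (see above).
- The built-in folder's energies are model units, not kcal/mol.
- The per-site PRF likelihood integrates γ out by quadrature rather than
  sampling per-site latent coefficients; for extremely heavy-tailed class
  distributions the 32-node Hermite rule would need raising.
- MAF parse errors name the offending block's ordinal, not a file line
  number.
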