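# ucekit

Discovery and characterization of **ultraconserved elements (UCEs)** —
genomic intervals that show zero substitutions and zero indels across a
whole clade of aligned genomes. The package targets the Drosophila-style
setting (a 12-genome multiz alignment anchored on a reference assembly,
population resequencing of the reference species) but every stage runs on
standard formats and on synthetic data with known ground truth.

It answers three questions about perfectly conserved intervals:

1. **Are they improbable under neutral divergence?** A background
   substitution model (HKY85 or JC69 on a fixed tree) is fit by maximum
   likelihood over alignment columns via Felsenstein pruning. For an
   element of length *L* the per-column probability *q* that all leaves
   show the identical base gives a conservation p-value *q^L*, and a
   likelihood-ratio test fits a rate-deceleration scale λ ∈ [λ_min, 1]
   against the boundary null (50:50 χ²₀/χ²₁ mixture).
2. **Are they selectively constrained rather than mutational cold spots?**
   From derived-allele frequency spectra at segregating sites, a
   hierarchical Bayesian model estimates the mean μ_c and variance σ²_c of
   the distribution of scaled selection coefficients γ = 2Ns for new
   mutations in each site class (UCE, flanking, nonsynonymous, ...). The
   per-site sampling probability follows the Poisson random field form
   P(i | n, γ) ∝ ∫₀¹ C(n,i) x^i (1−x)^{n−i} f(x; γ) dx with
   f(x; γ) = (1 − e^{−2γ(1−x)}) / ((1 − e^{−2γ}) x(1−x)), conditioned on
   segregation so the mutation rate cancels. Posteriors come from
   Metropolis–Hastings chains run from overdispersed starts; convergence
   is checked with the Brooks–Gelman multivariate PSRF, and an optional
   exponential zero-fixation weight corrects for divergence-based
   ascertainment of the elements.
3. **Do they look like structured RNAs?** Each element is folded (built-in
   stacking-aware Nussinov dynamic program, or an external
   Vienna-compatible backend) and its minimum energy is standardized
   against exact dinucleotide-preserving shuffles (Altschul–Erickson) as a
   z-score, plus base-composition (core vs flank A+T, Wilcoxon rank-sum)
   and per-base-pair annotation overlap classification.

A synthetic-data module generates every input the pipeline consumes —
alignments evolved on a tree with planted zero-rate elements, frequency
spectra drawn from per-class Normal(μ, σ²) distributions of 2Ns, sequences
with controlled dinucleotide composition, and toy gene annotations — so
the full pipeline is testable end to end without downloads.

## Worked example

A self-contained simulated run (five planted elements on a 30 kb
12-species alignment; SFS classes with means near −20 and −2):

```bash
ucekit run --simulate --seed 42 --genome-length 30000 \
    --chains 3 --iters 20000 --shuffles 50 --out-dir demo
ucekit report demo
```

prints, among other sections:

```
## Element length distribution
elements: 5  min: 80  max: 192

## Selection coefficients (2Ns) by site class
   site_class  n_snps  posterior_mean        map     ci_low    ci_high
          UCE     137      -15.464466 -14.171307 -21.205386 -10.958369
     flanking    1000       -2.358529  -2.443407  -2.930806  -1.851540
nonsynonymous    1000       -2.404996  -2.593720  -2.945854  -1.992618
truth (mu, sigma2): {"UCE": [-20.0, 4.0], "flanking": [-1.9, 1.0], "nonsynonymous": [-2.6, 1.0]}
PSRF: 1.0101

## Phylogenetic conservation tests
    name   L  q_identity       p_value  lambda_hat    lrt_stat         lrt_p
chrSim.1  80    0.057804 9.055852e-100    0.000001  458.200432 5.922157e-102
...
```

Reading it: the scan recovered all five planted elements exactly; each is
astronomically improbable under the background model (per-column identity
probability 0.058, so p = 0.058^L); the UCE-like class's 95% credible
interval (−21.2, −11.0) covers its generating mean 2Ns = −20 from only 137
SNPs, an order of magnitude stronger selection than the flanking and
nonsynonymous classes, whose intervals sit near −2; PSRF ≈ 1.01 indicates
the three chains converged.

Individual stages are also exposed (`ucekit scan`, `ucekit phylo-fit`,
`ucekit phylo-test`, `ucekit selection`, `ucekit rna-zscore`,
`ucekit composition`, `ucekit annotate`, `ucekit simulate`), all thin
wrappers over the `ucekit.*` library modules.

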