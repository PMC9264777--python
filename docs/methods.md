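# Methods

## Model and assumptions

All evaluations are single-trait animal models `y = Xb + Za + e` with
`a ~ N(0, K σ²ₐ)` and homogeneous residuals. Fixed effects are categorical
factors (contemporary group, sex) and optional continuous covariates;
identifiability is handled by reference-level dropping (first level of every
factor when an intercept is fitted, the first factor keeping all levels
otherwise), with an explicit rank check that names confounded factors.
One record per animal per trait is assumed (first-parity style data);
animals may lack records entirely.

Three relationship structures are supported through the same solver, which
only ever sees K⁻¹:

* **Pedigree BLUP** — Henderson's sparse A⁻¹ built from Meuwissen–Luo
  inbreeding coefficients. Unknown parents are unrelated, non-inbred base
  animals; there are no unknown-parent groups or metafounders.
* **ssGBLUP** — H⁻¹ = A⁻¹ plus the genotyped-block correction
  τ(αG + βA₂₂)⁻¹ − ωA₂₂⁻¹ scattered onto the genotyped animals' equations.
  Defaults α = 0.95, β = 0.05, τ = ω = 1. G is VanRaden's linear matrix with
  observed allele frequencies of the current genotyped set (base-population
  frequencies are not available in practice); no further rescaling of G
  toward A₂₂ is applied beyond the α/β blend.
* **wssGBLUP** — the iterative loop: solve with G* = MDM′/k (D = I at
  iteration 1), back-solve SNP effects `â = (1/k)·D·M′·G⁻¹·û_g` with the
  blended G the solver actually used, weight `dᵢᵢ = 1.125^(|âᵢ|/sd(â) − 2)`
  with the exponent capped at 5 (|â|/sd capped at 7) so no single marker can
  dominate, normalize D so `Σ dᵢ·2pᵢqᵢ` is conserved, rebuild G* and H⁻¹,
  re-solve. Three iterations by default: accuracy typically peaks by the
  third round, and later rounds mostly reshuffle extreme weights.

Because columns of M are centered, an unblended G is singular (null vector
**1**): the back-solve verifies its Cholesky solve and falls back to the
minimum-norm least-squares solution, so the consistency identity M·â = û_g
holds exactly whenever û_g lies in the range of G (i.e. up to the mean of
û_g), and approximately (correlation > 0.99) under the default blend.

Reliability is the printed-formula `Rel = 1 − PEV/σ²ₐ`, clipped to [0, 1],
with **no** (1 + Fᵢ) inbreeding adjustment; PEV is the animal-block diagonal
of the inverse coefficient matrix times σ²ₑ. An isolated, recordless animal
gets PEV = σ²ₐ and reliability 0; a single recorded animal with no fixed
effects gets reliability exactly h².

## Variance components

EM-REML with the classic updates

```
σ²ₐ ← (û′K⁻¹û + σ²ₑ·tr(K⁻¹C^{uu})) / q
σ²ₑ ← (y′y − b̂′X′y − û′Z′y) / (n − rank X)
```

iterated to a relative change below 1e-6. After absorbing the fixed effects,
the animal block of the MME is `Z′SZ + λK⁻¹`; a one-time generalized
eigendecomposition of (Z′SZ, K⁻¹) turns every EM round into O(q) arithmetic
(û′K⁻¹û and the trace are sums over eigenvalues), which is why the iteration
cap can be generous (20 000) — EM provably crawls when heritability is low
and thousands of rounds are normal at h² ≈ 0.1. σ²ₐ can be held fixed to
estimate σ²ₑ alone. Desk scale: the eigendecomposition is dense, so
pedigrees up to ~5000 animals are the intended regime.

## Genotype QC

Filters run in a fixed, pinned order so reports are reproducible:
animal call rate (> 10% missing removed) → SNP call rate (> 10%) → MAF
(< 5%) → Hardy–Weinberg (1-df chi-square goodness of fit, threshold 1e-6,
only for SNPs with ≥ 10 calls) → Mendelian conflicts (opposite homozygotes
in parent–offspring pairs; the offspring is removed when the conflict rate
with a recorded parent exceeds 1% of co-genotyped loci — its recorded
parentage is presumed wrong). Residual missing calls are then mean-imputed with
2pᵢ, which keeps allele frequencies unchanged and centered column means at
exactly zero. An array-intensity (GC/GT score) filter cannot be applied to
dosage data and is recorded in the report as not applied. The pipeline is
idempotent: a second pass removes nothing.

## The synthetic population generator

The generator emulates the structure of a nucleus pig-breeding dataset:

* discrete generations under random mating; founders unrelated; each female
  of a generation mated once to a random male, `offspring_per_mating`
  offspring each; offspring sexes balanced-at-random within a cohort so
  generation sizes stay stable;
* gene dropping at unlinked biallelic loci (chromosome labels exist in the
  marker map, but there is no recombination map): founder allele
  frequencies uniform in `founder_maf_range`, offspring inherit one allele
  per locus from each parent by fair coin, independently across loci;
* QTL are a designated subset of the genotyped SNPs with gaussian,
  signed-gamma (shape 0.4 — a few large effects) or equal-magnitude effects;
  effects are drawn once and rescaled so the realized TBV variance equals
  the target additive variance (heritability, with phenotypic variance ~1);
* phenotype = CG effect + sex effect + TBV + ε, with Var(ε) set from the
  realized TBV variance as Var(TBV)(1−h²)/h²; the `weight` column is a
  nuisance covariate with no effect on the trait;
* genotyping fractions per generation give the genotyped set; nested
  reference-group scenarios are generation-of-birth cutoffs.

What it deliberately does **not** emulate: linkage disequilibrium and
recombination (QTL–marker association is exact by identity, the regime where
SNP weighting is most clearly useful), selection and assortative mating,
overlapping generations, genotyping error. Passing tests on these
populations therefore demonstrate the algebra and the qualitative method
ordering, not field performance on real LD structure.

Two generator regimes matter for interpretation:

* **Oligogenic** (default 30 QTL among 1000 SNPs, h² = 0.4): where weighted
  ssGBLUP visibly beats plain ssGBLUP.
* **Fully polygenic** (every SNP causal, equal magnitudes): the weighting
  gain collapses (|Δr| < 0.02), the known caveat of nonlinear weighting.

For REML parameter recovery the fully polygenic gaussian architecture is
used: with few QTL the realized relationships at the causal loci scatter
around the pedigree expectation A with variance ~1/n_QTL, and an A-based
REML absorbs the excess family resemblance into σ²ₐ (measured as a +0.04
bias at h² = 0.3 with 200 QTL; unbiased with 1000).

## Problem sizes and numerics

The package targets desk scale by design: dense tabular A (O(n²) memory),
dense inversion of the genotyped blocks (n_g up to ~3000), one dense
Cholesky per MME solve (O(n³)), explicit inverse only when PEV/reliability
is requested. The bundled studies use 5 generations × 1000 animals (5000
total, 1000 genotyped, 500 validated candidates) for method comparison and
~2000 animals for REML recovery; each method-comparison replicate takes
~10 s on one CPU. Blended genomic matrices are checked positive definite via
the smallest eigenvalue (tolerance −1e-8 relative to the mean diagonal, so
PSD-within-noise inputs pass); singular MMEs and non-PD blends raise errors
naming the remedy. Ties in top-SNP selection break by marker-map order;
`sd(â)` is the population (ddof = 0) standard deviation over all SNPs.

## Forward validation

`make_partial_dataset` deletes the validated animals' phenotype records and
blanks the validated animals out of their progeny's sire/dam slots (the
progeny keep their own records; the validated animals keep their own
parents). Genotypes stay in the reference group — the protocol hides
phenotypes, not genotypes. Predictions from the partial data (parent
average, GEBV) are compared with whole-data estimates or simulated truth via
Pearson correlation and the dispersion regression `final = b₀ + b·prediction`
(b = 1 means no inflation); a mean-difference bias column is included.
Degenerate comparisons (constant vectors, e.g. all-unit weights) are
reported as not-applicable rather than raising.

## Known limitations

No multi-trait models, no unknown-parent groups or metafounders, no APY or
other large-n approximations, no per-SNP significance tests, no genotype
phasing/imputation beyond mean fill. The generator's unlinked-locus model
overstates how cleanly SNP weights can localize signal relative to real LD;
accuracy gains measured here are upper-bound-flavored for that reason.
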