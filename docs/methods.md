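# Methods

## Relationship kernels

**Microbiome kernel.**  The relative-abundance matrix S (n samples × v
taxa) is transformed to H by adding a pseudocount of 1e-5, taking logs,
and z-scoring each taxon column; the kernel is M = H Hᵀ / v.  Two
conventions needed fixing:

* *Standard deviation divisor.*  The z-score uses the **sample** standard
  deviation (n−1).  Under that convention every retained column
  contributes exactly n−1 to trace(H Hᵀ), so trace(M) = n−1 — an identity
  asserted throughout the tests.  Population-sd (n) would scale M by
  n/(n−1) and leave all variance *ratios* unchanged, so the choice does
  not affect h²/m².
* *Zero-variance taxa.*  Columns constant across samples carry no
  information and are dropped with a logged warning rather than an error,
  because prevalence-filtered tables can still contain constants after
  subsetting.  Partition kernels M1 (heritable taxa, p columns) and M2
  (non-heritable, q columns) use the same construction; for disjoint
  partitions p·M1 + q·M2 = (p+q)·M exactly.

**Genomic kernel.**  VanRaden method 1: Z = X − 2p per SNP (p = ALT
frequency), G = Z Zᵀ / (2 Σ pᵢ(1−pᵢ)).  Monomorphic and sub-MAF SNPs
(default MAF < 0.05) are excluded and counted.  No LD pruning and no
alternative (Yang/GCTA method-2) weighting.  Kernels are validated for
symmetry (1e-10) and positive semi-definiteness (smallest eigenvalue
above −1e-8 × largest); violations raise rather than being silently
repaired or bent, and kernels are never rescaled to mean diagonal 1.

## Variance-component estimation (AI-REML)

The mixed model y = Xβ + Σₖ uₖ + e with uₖ ~ N(0, σ²ₖ Kₖ) is fitted by
maximizing the restricted likelihood

  ℓ_R = −½ (log|V| + log|XᵀV⁻¹X| + yᵀPy),   V = Σ σ²ₖ Kₖ + σ²_e I,

over non-negative components.  Algorithmic choices:

* **Initialization** at var(OLS residuals)/(K+1) per component, followed
  by three EM warm-up steps (monotone, robust far from the optimum), then
  average-information (AI) Newton steps with step-halving whenever a step
  would decrease ℓ_R; if 20 halvings fail, the iteration falls back to an
  EM step.
* **Constraints.**  Components are clamped at a floor of 1e-8 × var(y);
  a component still at the floor at convergence is flagged as a boundary
  estimate and reported as exactly 0 (the "0.00" convention of variance
  tables).  When every component is on the boundary (e.g. a trait that is
  an exact function of the fixed effects) all ratios are reported as 0
  with all boundary flags set.
* **Convergence**: |Δℓ_R| < 1e-8 and relative parameter change < 1e-6,
  with a 200-iteration cap; non-convergence is reported in the fit
  record, not raised.
* **Identifiability.**  The AI matrix restricted to components away from
  the boundary is checked for conditioning; a singular AI matrix (e.g. an
  identity kernel competing with the residual) raises a dedicated error
  instead of returning arbitrary estimates.
* **Standard errors** come from the inverse AI matrix at the optimum;
  ratio (h², m²) standard errors use the delta method.  With boundary
  components the AI matrix is near-singular and the pseudo-inverse is
  used; those SEs are reported but flagged via the boundary indicators.
* **Single-kernel fast path.**  For one kernel the model is rotated into
  the kernel's eigenbasis, where V is diagonal and each iteration costs
  O(n·p²) instead of O(n³).  Both paths maximize the same function and
  are cross-checked against each other and against an exhaustive
  grid-search maximizer in the tests.  Taxon screens share one
  eigendecomposition across all taxa.
* **Log-likelihood constants.**  Additive constants (−(n−rank X)/2·log 2π)
  are omitted consistently in both the iterative and the closed-form
  null (residual-only) fits, so likelihood-ratio statistics are exact.

Significance of a single variance component uses the boundary-mixture
LRT: p = 0.5 · Pr(χ²₁ ≥ LR), i.e. the 50:50 mixture of χ²₀ and χ²₁
appropriate when the tested parameter sits on the boundary.  This is the
standard GREML convention; it is conservative in small samples, which
the null-calibration test (rejection rate in [0.01, 0.08] at nominal
0.05) makes explicit.

## Taxon screening and partitioning

Taxa are prevalence-filtered first (strict >, default 0.30 for ASVs and
0.60 for genera; a taxon exactly at the threshold is removed), then
CLR-transformed per sample over the retained taxa of that level:
x → log(x + 1e-5) − mean log(x + 1e-5).  The CLR pseudocount reuses the
kernel pseudocount since no separate value is prescribed.  Fixed effects
for the per-taxon fits are intercept, reference-coded breed, age in
months, and the top five genetic principal components, taken as
eigenvectors of the GRM (equivalent up to scaling to a PCA of the
centered SNP matrix; this avoids a second pass over genotypes).  The
heritable/non-heritable partition is defined at raw P < 0.05 with **no
multiple-testing correction** — deliberately, since the partition is a
screening device feeding the M1/M2 kernels, not a discovery list; the
chosen alpha is a parameter.  m²_h and m²_non are estimated in two
separate single-kernel fits (never one joint three-component model), and
average microbiability divides each by its taxon count: β²_h = m²_h/p,
β²_non = m²_non/q.  No SE is propagated to β² (point estimate only);
estimates below their SE are flagged "negligible" without altering the
stored values.

## Mediation

Exposure x is the CLR abundance of one heritable taxon, standardized to
unit variance so effects are per SD of exposure (the input scale is
otherwise arbitrary).  The mediator model m = α₀ + a·x + α_a·age and
outcome model y = β₀ + c′·x + b·m + β_a·age are ordinary least squares;
point estimates are ACME = a·b, ADE = c′, total = a·b + c′ (an exact
identity for linear models).  Inference is a nonparametric bootstrap
(default 1000 resamples of rows with replacement, refitting both
models): percentile 95% CIs — percentile rather than BCa, matching the
common default — and two-sided p-values
2·min(#{boot ≤ 0}, #{boot ≥ 0})/n_boot floored at 2/n_boot.  The
proportion mediated acme/total is reported as NaN when |total| < 1e-12.
Candidate taxa pass a Spearman union prefilter first (retained iff
P < 0.05 against at least one outcome trait; constant vectors give
undefined correlations and count as non-significant).  Triplets are the
full genus × mediator × trait product in genus-major order, each with a
bootstrap seed derived deterministically from the panel seed, so results
are reproducible and independent of evaluation order.

## Synthetic-data generator

The generator emulates the statistical structure the estimators assume,
at the cohort's design points: three breeds, ages uniform on 8–69
months, biallelic SNPs with base MAF uniform on (0.05, 0.5) and
breed-level frequency perturbations of standard deviation
`breed_fst_like_shift` (Fst-like divergence, no LD).  Per taxon, latent
log-abundance = breed intercepts (sd 0.5) + genetic value + noise; the
genetic value is polygenic-but-sparse (Gaussian weights on a random 1%
of SNPs, at least one) and every variance component is rescaled
*empirically* so realized variance fractions equal their targets exactly
— this makes recovery tests tight rather than adding sampling noise on
top of estimation noise.  Latent values are exponentiated, the smallest
values per taxon are zeroed to match the target prevalence exactly, and
rows are renormalized to compositions.  Traits are built on a unit
"core" variance (genetic h², microbial m² via the standardized
log-abundance matrix, residual 1−h²−m²); mediator paths and age effects
add variance on top of the core, so realized fractions — recorded in the
truth record — equal the targets only when those paths are absent.  All
randomness flows from one integer seed through named
`numpy.random.SeedSequence` child streams (genotypes, age, microbiome,
mediators, traits), making each stage reproducible in isolation.

What the generator does **not** emulate: sequencing depth and count
noise, LD structure, phylogenetic correlation between taxa,
over-dispersion beyond log-normality, and genuine confounding between
diet/environment and the microbiome.  Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
assumptions, not robustness to real-data violations of them.

One consequence worth knowing: because the simulated microbiome is
itself heritable, the G and M kernels are correlated, and the joint fit
shows the same mild h²/m² trade-off expected in real data (a percent or
two of genetic variance can surface in m̂² and vice versa).  Similarly,
the CLR's geometric-mean denominator leaks a small amount of heritable
signal into non-heritable taxa, so null-taxon false-positive rates in
mixed panels run slightly above the all-null calibration.

## Quality control and data handling

SNP QC applies, in order: removal of unplaced/sex-chromosome markers,
sample call-rate ≥ 0.90, SNP call-rate ≥ 0.90, MAF ≥ 0.05 (all
exclusions strict in the "< threshold" direction; equality keeps).
Remaining missing genotypes are mean-imputed per SNP — a deliberate
simplification of haplotype-based imputation that is irrelevant to
estimator correctness at the missingness levels QC permits, and logged
in the QC record.  Phenotype missingness is handled by per-trait
listwise deletion with logged counts.  All writers emit plain text with
17 significant digits and all readers parse with round-trip float
precision, so numeric payloads survive a write/read cycle bit-exactly.
Pipeline runs write a manifest (seed, configuration hash, per-stage row
counts) that is byte-identical across reruns of the same configuration.

## Problem sizes used in validation

Simulation-based checks run at n = 600–800 individuals, 1500–2000 SNPs
and 100–300 taxa (20 replicates for recovery means, 200 taxa for null
calibration), sizes at which Monte-Carlo error on a 20-replicate mean of
h² is ≈ 0.02 and the documented tolerances (±0.05–0.07) are meaningful.
The exhaustive grid-search oracle runs at n ≤ 10 where a 0.01-step scan
of the whole parameter box is feasible.
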