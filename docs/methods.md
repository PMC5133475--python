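# Methods

This note documents the statistical models implemented in `famassoc`, the
defaults and numerical choices, what the synthetic data generator does and
does not emulate, and the design decisions taken where the procedure was
genuinely open.

## Phenotype preparation

Longitudinal blood-pressure records (SBP, DBP, binary hypertension status,
over E exams with age, smoking and antihypertensive-medication covariates)
are collapsed to one quantitative value per individual:

1. derive MAP = 2/3·DBP + 1/3·SBP and PP = SBP − DBP where requested
   (both require SBP > DBP; PP is strictly positive by construction);
2. within each exam, replace the trait by its least-squares residual on
   (age, smoking, medication) across individuals;
3. average each individual's residuals over their available exams;
4. z-standardize (mean 0, variance 1).

Individuals with no non-missing exam are absent from the output, never
zero-filled. Constant covariates are dropped with a warning. The
adjust-then-average order is a design choice — the alternative
(average raw values, adjust once) is available via `order=
"average_then_adjust"`; on the synthetic data the two agree closely
(r > 0.9) but they are not identical, and no claim is made that either
matches any particular published pipeline exactly. Binary hypertension
passes through the same pipeline as a 0/1 quantitative trait, mirroring the
practice of applying linear mixed models to it alongside the pressure
traits.

## Kinship estimation

The realized relationship matrix (RRM) is K = WWᵀ/m over the m polymorphic
SNPs, with each dosage column mean-imputed (missing values), centered and
scaled to unit variance, so a missing genotype contributes exactly zero.
The centered estimator CCᵀ/m omits the variance scaling (the GEMMA-style
default, `-gk 1` flavor); both are exposed because published analyses
rarely state which was used and the tests confirm they agree up to per-SNP
scale when allele frequencies are equal. Monomorphic SNPs are excluded from
m with a logged count; no further MAF filtering is applied. `repair_psd`
clips negative eigenvalues at a floor (default 0), the Frobenius-nearest
clipped reconstruction, guaranteeing the spectral solver a valid
covariance.

The pedigree-expectation matrix Φ (kinship coefficients from the standard
recursion) is used as the simulation's polygenic covariance (2Φ) and as a
test oracle — E[RRM] ≈ 2Φ entry-wise — not as an analysis matrix. Note the
sample-frequency centering in the RRM shifts off-diagonals down by a term
of order (1 + mean relatedness)/n; the expectation checks therefore use
many small families, where the shift is negligible against the ±0.05
tolerance.

## Mixed-model fitting

For y = Xβ + g + ε with g ~ N(0, σ²_g K), ε ~ N(0, σ²_e I): eigendecompose
K = USUᵀ once, rotate y and X by Uᵀ, and profile the likelihood down to the
single parameter δ = σ²_e/σ²_g, for which the GLS solution and variance
estimates are closed-form. Numerical choices:

- δ grid: 64 log-spaced points on [1e−5, 1e5], then bounded scalar
  refinement (in log₁₀ δ, absolute tolerance 1e−7) between the best grid
  point's neighbors; ties take the smaller δ. The returned likelihood is
  never below the best grid value (asserted in tests).
- ML is the default for every likelihood-ratio test, so nested statistics
  are valid; REML is available for variance reporting (it protects the
  variance components from fixed-effect degrees-of-freedom loss but REML
  likelihoods are not comparable across different X).
- δ is fully re-optimized under each model in a nested comparison, the
  conservative reading of "maximum likelihood under each model"; reusing
  the null δ would be cheaper but is not what nested ML means.
- Negative LRT values from optimization jitter are clamped to 0 (p = 1);
  values below −1e−8 are logged.
- K eigenvalues in [−1e−8, 0) are clipped to 0; anything lower raises an
  error directing the caller to `repair_psd`.
- Rank-deficient designs raise; individuals missing a SNP's dosage are
  dropped for that SNP only, and missingness patterns share their
  eigendecomposition.

Single-SNP association uses the ML likelihood ratio against χ²₁ rather than
an F- or Wald test; at the sample sizes involved the variants agree to
asymptotic order (tested: |p_Wald − p_LRT| < 0.002 at n = 1900), and one
inferential path keeps single-SNP and interaction tests comparable. With
K = I the fitted coefficients equal OLS to 1e−8 and the plain-regression
path (`ols_assoc`, Wald t-test with covariates) covers unrelated samples.

## Interaction testing

M0: intercept + d₁ + d₂; M1: M0 + d₁·d₂; both by ML with the same δ
machinery, LRT vs χ²₁. Swapping the SNPs leaves the statistic unchanged,
and recoding either SNP to major-allele counts leaves the p-value unchanged
because {1, d₁, d₂, d₁d₂} and {1, 2−d₁, d₂, (2−d₁)d₂} span the same column
space. Degenerate configurations (product collinear with the mains, e.g. a
SNP with no heterozygotes aligned so d₁d₂ is a linear function of the
mains) raise with the degeneracy named. At least 10 complete individuals
are required; both SNPs must be polymorphic in the analysis subsample.
Expression traits are covariate-adjusted upstream via the same
least-squares machinery as the blood-pressure phenotypes (single "exam"),
so the interaction design carries no covariate columns beyond the
intercept and the two dosages.

## Combined set test

T = −Σ log₁₀ pᵢ. Monte-Carlo null: draw Z ~ N(0, R), set pᵢ = 2Φ(−|Zᵢ|)
(two-sided tail, since the constituent association p-values are two-sided),
compute T, and report the strictly-greater tail proportion — strict
counting without add-one smoothing is the primary definition; a
conservative (b+1)/(B+1) variant is available (`add_one=True`). Defaults:
500,000 replicates for phenotype panels, 10,000,000 for the expression
panel, both overridable; sampling is chunked (500k × n per chunk) so the
10⁷-replicate run stays within ordinary memory.

The latent correlation model R:

- SNP-level correlation is +√(r²) for same-chromosome SNPs closer than
  2 Mb (open window), 1 for a SNP with itself, else 0. PLINK-style r²
  destroys the allelic sign, so the positive root is an approximation that
  can only overstate dependence; it is exact at r² ∈ {0, 1}.
- Between two interaction tests, the correlation is the product of the two
  constituent SNP correlations under the pair alignment maximizing the
  product — exact for bilinear forms of independent Gaussians and correct
  in both limits.
- Tests declaring different response traits (`TestEntry.trait`, e.g.
  different expression probes) are independent under the null regardless
  of SNP sharing: the null randomness lives in the trait vector, and
  distinct probes are distinct independent measurements. This matters for
  panels where one SNP pair is tested against two probes — treating those
  rows as perfectly correlated would inflate the null tail of T by nearly
  an order of magnitude at the observed statistic. When no trait ids are
  given, all tests are assumed to share one response (the single-phenotype
  panel case) and SNP sharing implies correlation.
- R is PSD-repaired before sampling.

Under independence the exact null is available in closed form
(T·ln10 ~ Gamma(n, 1), equivalently 2·ln10·T ~ χ²₂ₙ): `fisher_independent`
is both a fast path and the oracle against which the Monte-Carlo sampler is
verified (agreement within 3 binomial SE). Bonferroni thresholds are
reported exactly, with a 2-significant-figure display helper matching
conventional reporting; Benjamini–Yekutieli adjustment implements the
step-up rule with the harmonic-number penalty and is cross-checked against
statsmodels in the tests.

## Power

For an additive single-SNP effect β on a quantitative trait with residual
standard deviation σ in n unrelated individuals, the 1-df test has
noncentrality λ = 2·maf·(1−maf)·n·β²/σ², and power is the
noncentral-χ²(1, λ) tail beyond the central χ²₁ critical value. A
variance-explained parameterization (λ = n·r²/(1−r²)) is provided for
meta-analysis-reported effects. Family designs are less informative per
individual, so these are upper limits when applied to related samples —
e.g. at n = 954 and variance explained between 0.05% and 0.3%, power at
α = 0.05 spans roughly 0.10–0.39, consistent with the weak replication
power typical of family cohorts of this size.

## Synthetic data generator

What it emulates, per `SimConfig` (defaults in parentheses):

- **Pedigrees** (20 families, ~48 members, 3 generations): one founder
  couple per family; children per couple ~ Poisson(c) with c solved so the
  expected family size matches; pre-terminal children marry in founder
  spouses. Expected cohort ≈ 950–960 individuals, the scale of the target
  design.
- **Genotypes**: founder haplotypes from a latent Gaussian AR(1) threshold
  model — within a block of `block_size` (10) SNPs the latent field has
  lag-1 correlation `within_block_r` (0.8) and the minor allele is carried
  where the latent value falls below Φ⁻¹(maf), maf ~ U(0.05, 0.5) per SNP;
  blocks are independent. Gene dropping transmits one parental haplotype
  per block independently (free recombination between blocks, none
  within). Blocks sit 5 Mb apart (1 kb marker spacing within), so the
  2 Mb LD window sees within-block pairs only. Founders satisfy
  Hardy–Weinberg; the thresholding makes realized haplotype correlation
  somewhat lower than the latent parameter, which is immaterial here —
  the analyses need LD to exist, not to match a map.
- **Phenotypes** (4 annual exams, 5% missed-exam rate): DBP = 75 +
  Σβⱼdⱼ + 0.4·age + 3·smoking − 5·medication + polygenic + noise, with
  polygenic covariance σ²_g·2Φ, heritability h² (0.3) fixing
  σ²_g = h²/(1−h²)·σ²_e, and residual SD 8 mmHg; SBP = DBP + a strictly
  positive pulse-pressure draw; hypertension = SBP ≥ 140 or on medication
  (any monotone link suffices for pipeline testing — no generative claim);
  ages advance 1 year per exam from a generation-dependent baseline.
- **Expression**: e = 5 + a₁d₁ + a₂d₂ + γ·d₁d₂ + polygenic + noise, with
  γ = `interaction_effect` (0.5) and unit residual SD.

One master seed streams named substreams to every stochastic operation, so
a dataset is bit-reproducible and operations are independently re-runnable.

What it does **not** emulate: sequence-level variation, imputation error,
genotyping-chip ascertainment, admixture or ethnicity structure,
medication-dependent measurement artifacts, realistic recombination maps.
Passing tests therefore demonstrate the statistical machinery is calibrated
and correct under a faithful family/LD/polygenic structure — not that any
particular real cohort would yield the same per-SNP results.

## Problem sizes used in the checks

The calibration checks run at sizes chosen to make their asymptotics and
tolerances meaningful: type-I error of the single-SNP and interaction LRTs
on 1000 null replicates over a fixed 6-family, ~250-person structure with
common variants (the χ²₁ approximation is visibly anticonservative for
rare-variant product columns at n ≈ 100, a property of the test, not a
defect of the implementation); RRM expectation checks on 40 small families
(sample-centering shift ≪ tolerance); heritability recovery at the full
20-family, ~950-person design over 20 replicates; the combined-test
reproduction at 10⁷ (14 tests) and 10⁶ (12 tests) replicates.

## Known limitations

- The +√(r²) latent correlation is validated only at the independence and
  perfect-correlation limits; intermediate dependence is an approximation.
- The longitudinal reduction is one reasonable reading of "average
  quantitative trait" adjustment; published pipelines differ in
  unrecoverable details (adjust/average order, covariate sets).
- The LMM path does not implement low-rank speedups; it targets cohorts of
  a few thousand individuals at most.
- HTN is analyzed as a 0/1 quantitative trait, not by a generalized mixed
  model; its p-values inherit the usual caveats of linear probability
  models.
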