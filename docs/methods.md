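# Methods

## The phenotype and its covariate model

The analysis outcome is maximum hand grip strength (kg) over the two hands;
a sample with at least one measured hand keeps that hand's value. Samples
are excluded, in order and at most once each, for: COPD, brachial plexus
disorder, arm/wrist/hand injury history (input flags; ICD-code parsing is
upstream curation), body weight missing or outside the closed 30–200 kg
window, and grip missing for both hands. The exclusion audit satisfies
`rows_in = rows_out + Σ removals` exactly.

Association models adjust for 20 genetic principal components and an
anthropometric polynomial: age, sex, age², age×sex, age²×sex, height,
height², height×sex, height²×sex, plus an intercept (30 design columns).
Age and height are mean-centered before squaring; this improves conditioning
and leaves the burden coefficient unchanged. An optional per-sample offset —
a polygenic predictor of the phenotype — is subtracted from the response
before fitting, so any constant shift in the offset is absorbed by the
intercept.

## Qualifying variants and burdens

A rare variant (MAF < 0.1%, from the annotation table, not recomputed from
the cohort) qualifies as:

- **PTV** if its consequence is stop-gained, splice-disruptive or frameshift
  *and* LOFTEE labels it high-confidence; low-confidence calls are excluded.
- **missense_gt30 / missense_20_30 / missense_0_20** by CADD phred, reading
  the bin edges literally as `>30`, `(20, 30]`, `(0, 20]`. CADD = 30 falls
  in the middle bin and CADD = 0 in no bin; a missense variant with missing
  CADD is an error, never silently binned.
- **synonymous** as a negative-control class.

Genes are stratified by pLI at 0.9 (≥ 0.9 = LoF-intolerant); the five
classes × {all, intolerant, tolerant} give the 15 exome-wide categories.
Burdens are integer sums of alt-allele dosages per gene; missing dosages
contribute 0 (mean imputation exists but is off by default); the burden can
optionally be collapsed to a 0/1 carrier indicator. Gene-set and exome-wide
burdens are exact column sums, so conservation (exome = Σ genes) holds in
integer arithmetic. Genes with fewer than 10 carriers (a carrier has burden
≥ 1; exactly 10 is kept) are dropped before gene scans.

## Association testing

Each burden test is OLS with a two-sided t-test for the burden coefficient
at the residual degrees of freedom (not a normal approximation). Scans over
many units use the Frisch–Waugh–Lovell decomposition: the phenotype and all
burden columns are residualized on the covariate design once (via its QR
factorization), and each unit then reduces to a simple regression with
`df = n − p_design − 1`. This is algebraically identical to per-unit full
OLS — the equivalence is itself a test — and keeps a 2,000-gene scan at
n = 20,000 to a few seconds.

Multiple testing: Bonferroni thresholds are α/m reported at two significant
figures (the convention for printed thresholds; significance flags against
both the raw and rounded threshold are recorded), and FDR uses a
Benjamini–Hochberg step-up written here directly (it is a core specified
operation) and cross-checked exactly against `statsmodels` and against a
brute-force `min_{j≥i} p_(j)·m/j` oracle.

Sex-stratified scans refit each stratum with the sex main effect and all
sex interactions removed, and report a heterogeneity z-score
`(β_m − β_f)/√(se_m² + se_f²)`. The X-chromosome scan removes
sex-aneuploidy-flagged samples, accepts only X genes, and by default doubles
male (hemizygous, 0/1-coded) burdens so a male rare allele counts like a
diploid homozygote; 0/1 coding is a flag.

**LOCO offsets.** Whole-genome regression (regenie-style) is simplified to
ridge regression of the covariate-residualized phenotype on standardized
common-variant dosages: one penalty chosen by 5-fold cross-validation on the
full variant set, then for each chromosome a ridge fit on all *other*
chromosomes' variants provides that chromosome's offset — the offset for
chromosome c has exactly zero weight on chromosome-c variants. Externally
computed offsets can be supplied instead wherever an `offset` argument is
accepted.

**Overlap analysis.** Lead variants with MAF > 0.01 define closed ±500 kb
windows; a gene overlaps if its body intersects the window (a gene starting
exactly 500,000 bases from the lead is in). Overlap genes are joined to the
burden scan and tested against Bonferroni over the overlap-gene count.

## PheWAS

Binary traits (0/1) need ≥ 100 cases (exactly 100 passes). Quantitative
traits need ≥ 100 observations and ≥ 12 distinct values, then values more
than 5 SDs from the pre-trim mean are set missing in a single pass — the
moments are deliberately not recomputed, as iterative trimming would change
the sample definition. The two-step scan runs a maximum-likelihood logistic
screen (covariates: 20 PCs, age, sex, age², age×sex, age²×sex — no height
terms, since height belongs to the phenome being scanned) and refits pairs
with screen p < 0.01, plus any pair whose screen failed to converge, with
Firth regression. Quantitative traits get paired linear tests on the raw and
rank inverse-normal-transformed scale.

**Firth solver.** The estimate maximizes ℓ(β) + ½ log det I(β). The solver
runs Fisher scoring on the hat-adjusted score U*(β) = X′(y − μ + h(½ − μ))
with strict-ascent step-halving; because the scoring direction uses the
unpenalized information, it contracts only linearly and can two-cycle around
the optimum on very small tables, so a stalled or unconverged iteration is
polished by an exact Newton solve of U*(β) = 0 with a finite-difference
Jacobian. Convergence requires max |U*| < 1e-9 (tight enough that the 2×2
slope matches the Haldane–Anscombe closed form
`log[((a+½)(d+½))/((b+½)(c+½))]` to 1e-6 even under separation) within 200
scoring iterations. P-values are Wald on the penalized fit by default; a
penalized likelihood-ratio option is provided.

## Inverse-normal transformation

`z_i = Φ⁻¹((r_i − 0.375)/(n + 0.25))` with the Blom offset and average ranks
for ties — the quantitative-trait GWAS convention. Missing values stay
missing and consume no ranks; fewer than two distinct values is an error.
The displayed carrier comparison first divides grip strength by standing
height, residualizes on age, sex and PCs, then applies the INT.

## PRS and additivity

The evaluation set is every carrier of a qualifying PTV in the Mendelian
neuromuscular gene lists plus an equal-size seeded random draw of
non-carriers; training is the remainder, and weight building never sees
evaluation samples (asserted by id audit). Weights are GWAS betas at
p < threshold — a deliberate, documented stand-in for posterior-shrinkage
weighting; externally produced weight files drop in unchanged. Scoring
orients on the effect allele (dosage reflected as 2 − d when the effect
allele is the reference), keeps per-chromosome partial scores, and sums
chromosomes 1–22. The additivity model adds to the full covariate design:
standardized PRS (within the fitted sample), dominant- and recessive-list
carrier indicators (a sample carrying both kinds gets both set), and the two
PRS×carrier interactions; categories without carriers are dropped with a
warning. "Additive" means no retained interaction is significant at α.

## Mouse pipeline

Per animal: mean of exactly 3 peak pull-force trials (grams) / femur length
(mm). Box-Cox chooses λ ∈ [−2, 2] by maximizing the profile log-likelihood
of `y^(λ) ~ cohort` with bounded scalar optimization (xatol 1e-6; boundary
hits are flagged); `y^(λ) = (y^λ − 1)/λ`, `log y` at λ = 0. The genotype
test is a double GLM: a Gaussian mean submodel `y ~ genotype + cohort`
(genotype as mutant-allele dose 0/1/2 by default; categorical optional) by
WLS with weights 1/φᵢ, and a gamma/log dispersion submodel of the
leverage-adjusted squared residuals on intercept + cohort (genotype
optionally addable), alternated until the extended quasi-likelihood changes
by < 1e-8 relative (cap 100, then an error with the trace). With constant
dispersion it reduces to OLS, which is tested. For display, residuals from
`transformed ~ cohort` (genotype signal retained) are converted to z-scores
against the wild-type mean and SD and compared by two-sided Welch t-tests
(pooled-variance optional).

## The synthetic cohort generator

The generator provides the statistical structure the analysis assumes, with
known truth; it does not model site-frequency spectra, demography,
relatedness, or sequencing error, so passing tests demonstrate correctness
of the statistical machinery, not robustness to those real-data features.

Defaults: rare MAFs log-uniform on (5e-5, 9.9e-4) (the rare ceiling 0.1% is
enforced by validation); variants per gene Poisson(6), ≥ 1; class mix
PTV 6.3% / missense 59.3% / synonymous 34.4%, proportional to the source
study's qualifying-variant counts (0.71M / 6.68M / 3.88M); 90% of
PTV-eligible variants LOFTEE high-confidence; CADD uniform on (0, 40] for
missense, [0, 10) for synonymous — only bin membership matters downstream;
18% of genes drawn with pLI ≥ 0.9. Genotypes are independent Hardy-Weinberg
binomials (rare variants carry no LD); common variants (MAF uniform, > 0.01
enforced) optionally get blockwise AR(1) haplotype LD through a Gaussian
copula. X-gene variants are haploid 0/1 in males.

Grip strength is a polynomial in age, sex and height with coefficients
chosen to mimic adult dynamometry (about 40 kg male / 24 kg female means,
decline after midlife), plus Σ_g effect_g × burden_g over the injected
effect table (acting through a configurable qualifying class, PTV by
default), plus an optional polygenic component built from standardized
common dosages and scaled so `polygenic_h2` is its share of non-covariate
variance, plus N(0, noise_sd²) noise with noise_sd = 5 kg. Both hands are
the latent value plus independent jitter (SD = 5% of phenotype SD), so the
analysis maximum tracks the latent signal; exclusion flags are drawn at the
source study's removal rates. The variance decomposition of real grip
strength across covariates/polygenic/noise is not identified by any printed
value, so these defaults are configurable rather than inferred.

Binary traits are Bernoulli at the stated prevalence, optionally linked to a
gene's carriers through a logistic model with stated log-odds. The mouse
generator defaults to the study's 24/18/13 WT/HET/HOM design in two cohorts
(baseline 120 g, animal SD 10 g, trial SD 6 g, femur 15.5 ± 0.4 mm, +8 g
second-cohort shift); genotype effects are gram shifts, so (−8, −16) is a
dose-dependent ~(−0.8, −1.6) animal-SD pattern.

## Problem sizes and numerical choices in the shipped checks

The acceptance script and end-to-end tests run at desk scale, chosen to make
each property measurable in about a minute total: null calibration on one
all-PTV cohort of 20,000 samples × 2,000 genes (all genes then pass the
carrier filter, so the scan covers the full panel); effect recovery with 200
noise replicates on fixed genotypes at n = 20,000 (conditional-on-genotype
replication isolates estimator bias, which is the claim under test, and the
injected magnitudes −0.25 kg exome-wide, −0.61 kg single-gene, +0.954 kg/SD
PRS and −0.196 kg dominant-carrier are the study-scale effect sizes);
additivity over 100 replicates at the 10,000-sample evaluation scale with
25% dominant / 25% recessive carrier draws; 100 random 2×2 Firth tables;
1,000 brute-force BH vectors; 50 mouse cohorts against a 1e-3 λ grid.

Known limitations: no LD for rare variants (collapsing tests are
LD-insensitive by construction, but annotation errors correlated along
haplotypes cannot be studied); the LOCO ridge is a one-penalty
simplification of blocked whole-genome regression; Firth inference is Wald
by default, which is conservative far from the null; the Box-Cox profile
likelihood is assumed unimodal on [−2, 2] (the grid oracle guards this);
listwise deletion is used per scan rather than joint missing-data modelling.
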