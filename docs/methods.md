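# Methods

`httgen` implements a two-arm statistical analysis of genetic contributions to
regional brain serotonin-transporter (5-HTT) availability, as measured by
[11C]DASB PET binding potential (BP_ND), together with a calibrated synthetic
cohort generator that makes every stage testable without access to restricted
participant data.

## Genotype coding

Five serotonin-related variants are dichotomized under a carrier model:
*BDNF* rs6265 (met carriers vs. val/val), *SLC6A4* 5-HTTLPR combined with the
adjacent triallelic A/G SNP (S′ carriers — at least one S or L_G allele — vs.
L_A/L_A), *HTR1A* rs6295 (G carriers vs. CC), *HTR2A* rs7333412 (G carriers
vs. AA), and *MAOA* rs1137070 (T carriers vs. CC). The triallelic SNP appears
in the source literature under two rs identifiers (rs25531/rs23351); the
package treats it as a single A/G locus. *MAOA* is X-linked: males are
hemizygous and contribute a single allele, and carrier status for a male is
the identity of that allele. The G allele of the triallelic SNP occurs only on
L backgrounds; a G called against an S/S diplotype is rejected as an
inconsistent haplotype. Missing genotypes are rejected, never imputed.

QC uses a plain Pearson 1-df chi-square test of Hardy-Weinberg genotype
proportions at the sample allele frequency (females only for the X-linked
variant; no continuity correction or exact test — the minimal defensible
default where no method detail is available), and a 2x2 chi-square comparing
male hemizygous allele frequencies with female allele frequencies at
rs1137070. Hardy-Weinberg is not assessed for 5-HTTLPR because genotype at
that locus was an inclusion criterion in the source studies.

## The latent-variable model

Regional BP_ND values are strongly intercorrelated, so the seven regions
(caudate, putamen, midbrain, thalamus, hippocampus, amygdala, neocortex) are
modelled as indicators of one latent factor. For participant i with covariate
row x_i (five carrier indicators, mean-centered age, sex, PET scanner, MRI
scanner):

    y_i = nu + lambda * eta_i + D x_i + eps_i,   eps_i ~ N(0, Psi)
    eta_i = gamma' x_i + zeta_i,                 zeta_i ~ N(0, tau^2)

with direct paths D for sex -> caudate and rs6265 -> neocortex and residual
covariance links for caudate-putamen, amygdala-hippocampus and
thalamus-midbrain. Identification fixes lambda_caudate = 1 and the latent
intercept at 0, so covariate effects on the latent factor are in caudate
BP_ND units (the reference scale). Sex is coded female = 0 / male = 1 and
scanners GE-Advance = 0 / HRRT = 1, Trio = 0 / Verio = 1, so a positive sex
estimate means higher male binding. The latent residual variance is only
estimable with at least three indicator regions: a one-region specification
degenerates exactly to OLS (tau^2 fixed at 0) and two-region specifications
are rejected as unidentified, as is any covariate given direct paths to every
region on top of its latent effect.

**Estimation.** The exact multivariate-normal likelihood is maximized with
the mean parameters (nu, gamma, delta) concentrated out by generalized least
squares at every covariance evaluation; the outer quasi-Newton (L-BFGS-B)
search runs over loadings, log variances and atanh residual correlations,
with up to five jittered restarts on failure. Starting values come from a
principal-axis decomposition of the covariate-adjusted region covariance.
Standard errors are obtained from the inverse of the numerically
differentiated observed information at the optimum; Wald 95% intervals and
two-sided normal p-values follow. A singular information matrix (e.g. at a
tau^2 = 0 boundary, which occurs occasionally in small samples) is reported
through `converged_ = False` rather than silently repaired.

**Model search.** Candidate edges are all absent direct covariate->region
paths plus all absent residual covariances. By default each candidate is
scored with a Rao (score) test at the fitted null — one extra parameter, one
degree of freedom, no refit — with gradients and information computed on the
unconstrained scale (log variances, atanh correlations), where every
finite-difference step stays inside the positive-definite cone; the Rao
statistic is invariant to that reparameterization. A refit-and-Wald
confirmation mode is available (`method="wald"`). Raw p-values are
Benjamini-Hochberg adjusted across the entire candidate set and edges with
adjusted p < 0.05 are reported as added. A genotype-block likelihood-ratio
test compares the full model against the model with all genotype-bearing
parameters removed (five latent effects plus the rs6265->neocortex direct
path; 6 df).

**Small-sample behaviour.** The chi-square reference for the per-candidate
1-df tests is asymptotic. At n = 140 its far tail is optimistic, and the
minimum over ~79 candidates amplifies this: simulations from the null model
show an any-discovery rate well above the nominal FDR at n = 140 that
disappears by n = 500 (the refit LRT shows the same behaviour, so it is a
property of the reference distribution, not of the score implementation).
Search results on cohorts of the study's size should be read as screening,
not confirmatory, evidence.

## Regional regressions and percent differences

Each region is separately regressed (OLS) on all five carrier indicators plus
age (centered), sex and both scanner indicators. The percent difference for a
genotype is 100 * beta_genotype / m_ref, where m_ref is the covariate-adjusted
reference-group mean: the fitted value with every genotype indicator at 0,
continuous covariates at their means and categorical covariates at their
sample proportions. This denominator makes the statistic invariant both to
rescaling of BP_ND and to covariate imbalance between genotype groups (the
published analysis does not define its denominator; this is the package's
choice). Constant (zero-variance) genotype columns are dropped from the
design and reported as inestimable.

## Prediction harness

Per region, BP_ND is first residualized on age, sex and the two scanner
indicators by OLS. The five carrier indicators are then used to predict those
residuals with a random-forest regressor under five-fold cross-validation:
squared errors are pooled across the five folds before taking the root (one
RMSE per fold assignment; a mean-of-fold-RMSEs variant is exposed as
`pooling="per_fold"`), and the procedure is repeated over `n_resamples = 10`
random fold assignments, reporting the mean. Significance is calibrated
against an empirical null obtained by permuting the residual vector and
re-running the entire repeated-CV procedure per permutation (default
`n_permutations = 10,000`; configurable down for testing). The test is
one-sided — improvement means lower RMSE — and uses the add-one convention
p = (1 + #{null <= observed}) / (B + 1), which guarantees p > 0. The seven
regional p-values are Holm adjusted. Improvement is summarized as
dRMSE = 100 (RMSE_residual - RMSE_genotype) / RMSE_residual, computed on
unrounded stored values (rounded two-significant-digit RMSE pairs generally
do not reproduce an unrounded dRMSE).

**Forest.** The learner mirrors classic random-forest regression defaults:
500 bootstrap trees, mtry = max(1, floor(p/3)) candidate features per split
(= 1 for the five genotype features), terminal nodes of size <= 5, forest
prediction the mean over trees. Features are inspected in random order and
only features that actually separate a node count toward the mtry budget, so
a node is terminal only when no feature separates it (or it reaches the size
floor). Because the features are a handful of binary indicators, every sample
is one of 2^p feature patterns and a bootstrap reduces to per-pattern counts
and sums; the in-repo implementation (numba) exploits this to fit a tree in
microseconds, which is what makes the fully nested permutation scheme
(repeated CV inside every permutation) tractable on one CPU. The
implementation is cross-checked against scikit-learn's RandomForestRegressor
in the test suite.

**Seeding.** A single root seed drives fold assignments, per-tree bootstraps
and permutations through independent derived streams; identical inputs and
seed give bitwise-identical reports.

## Synthetic cohort generator

The generator emulates the cross-sectional study the analysis is designed
for: n = 140 (84 female / 56 male), ages truncated-normal on 18-51 years with
the underlying parameters solved so the realized mean/SD equal 26.7/7.2, PET
scanner 42/98 (GE-Advance/HRRT), MRI 81/59 (Trio/Verio), and per-variant
carrier counts (S′ 99, rs6295-G 107, rs7333412-G 53, rs1137070-T 65,
rs6265-met 50). Marginal counts are exact by construction (shuffled
fixed-count assignment), and genotypes are independent across variants (their
joint distribution is unpublished). Regional binding follows exactly the
latent-variable model above.

Calibration closure. Planted effect sizes are the study's reported values:
gamma_MAOA = +0.07, gamma_rs6265 = -0.06 (met carriers lower; with a direct
rs6265->neocortex path of +0.06*lambda_neo so the neocortical total effect is
zero), gamma_age = -0.009 per year, direct sex->caudate = +0.14; all other
covariate effects default to 0. Regional percent-difference targets are
caudate 11, putamen 9, amygdala 2, and 6 elsewhere (midpoint of the reported
2-11 range). With lambda_caudate = 1, the target caudate percent difference
pins the covariate-adjusted reference-group caudate mean at 0.07/0.11 ~ 0.636;
since the sex->caudate path contributes at the male sample proportion, the
caudate intercept is mu_cau = 0.07/0.11 - 0.14 * (56/140) ~ 0.580. Other
regional means are configurable plausible values (putamen 0.75, midbrain
0.85, thalamus 0.65, hippocampus 0.35, amygdala 0.55, neocortex 0.25), and
loadings are derived as lambda_r = (pct_r/100) * mu_r / gamma_MAOA so that
latent-mediated effects reproduce the planted percent profile. Total
covariate-adjusted SD targets per region are (0.266, 0.301, 0.251, 0.305,
0.121, 0.272, 0.056); with latent residual SD tau = 0.15 (a configurable
choice), region residual variances are psi_r = sd_r^2 - lambda_r^2 tau^2
(configurations making any psi_r non-positive are rejected). Residual
correlations for the three covariance links default to 0.4 (caudate-putamen),
0.3 (amygdala-hippocampus) and 0.3 (thalamus-midbrain) — unpublished;
plausible for adjacent/functionally coupled regions.

Note that the covariate-only residual RMSE (the prediction arm's null RMSE)
retains the small genotype-effect variance, inflating the caudate value by
~0.7% over the 0.266 target, while the OLS degrees-of-freedom loss deflates
it by a similar amount; the net caudate residual RMSE across simulated
cohorts is ~0.265.

What the generator does not emulate: within-region measurement error
structure beyond Gaussian residuals, scanner-specific effect heterogeneity,
genotype linkage, lifestyle covariates, seasonal effects, or any image-level
artifact. Passing tests therefore demonstrate statistical correctness of the
estimators under the assumed generative model, not robustness to the ways
real PET data violate it.

## Problem sizes used in the shipped studies

The packaged simulation studies use: 200 cohorts of n = 140 for
parameter-recovery and percent-difference checks; 100 cohorts for the
dispersion check; 500 exchangeable-null simulations with B = 199 permutations
(forest scaled to 10 trees, 1 resample) for type-I calibration of the
permutation test, plus 100 seven-region null cohorts with B = 99 for
family-wise control; n = 10,000 single cohorts for asymptotic recovery; and
n = 500 replicates for FDR calibration of the model search. Permutation-test
calibration is a property of the permutation mechanism, not of forest size,
so small forests are used there; full-size forests (500 trees, 10 resamples)
are exercised directly in the prediction tests.

## Known limitations

* Wald intervals and score/LRT p-values rely on asymptotics; at n = 140
  coverage is slightly below nominal (~0.93-0.95 at n >= 1000 in the shipped
  coverage study) and model-search tails are optimistic (see above).
* tau^2 can hit the zero boundary in small samples (a Heywood-type solution);
  the fit reports it honestly and downstream Wald inference for variance
  parameters is then unreliable.
* The forest is specialized to at most 12 binary features by design; it is
  not a general-purpose learner.
* Percent differences divide by an estimated reference mean; regions with
  near-zero adjusted means would be unstable (not the case for any default
  region).
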