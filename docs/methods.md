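# Methods

This note documents the statistical models implemented in `methscore`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Methylation scores

A trait's methylation score for sample *i* is the raw weighted sum
`MS_i = Σ_j w_j m_ij` over the CpGs selected from an external MWAS at a
p-value threshold — no normalization by CpG count. Selection uses
`p ≤ cutoff` (ties at the cutoff are included; the convention is
arbitrary but fixed). The methylome-wide (MW) cutoff is the Bonferroni
level `alpha / n_tests` with `alpha = 0.05` and `n_tests` defaulting to
the number of CpGs in the MWAS file; source MWASs used study-specific
significance rules, so both values are overridable. Because the five
cutoffs are ordered, the selected CpG sets are nested
(MW ⊆ 0.01 ⊆ 0.05 ⊆ 0.1 ⊆ 0.5), a property the tests enforce on every
simulated recipe.

Scores are computed on the M-value scale by default
(`M = log2(beta/(1−beta))`), matching the analysis scale of the
pre-corrected cohort data; the scale of the original weighted sum is not
documented in the source analyses, so beta-scale scoring is equally
supported by passing a beta matrix. Whether scores are z-standardized
before regression is likewise undocumented; both raw and standardized
modes exist, and the pipeline default standardizes so coefficients read
as log-odds per SD. CpGs in a recipe but absent from the target array are
dropped and counted in an overlap report; no re-weighting is applied.
Missing methylation values are an error at this stage — imputation, if
any, is upstream.

## Preprocessing

The cohorts' mixed-model pre-corrections (technical, then
genetic/family random effects) require pedigrees and are out of scope.
They are replaced by fixed-effects residualization: each CpG is replaced
by its least-squares residual on an intercept plus chosen covariates,
after complete-case filtering with logged exclusion counts. Methylation
PCs are the right-singular-direction scores of the column-centered
(residualized) matrix; SVD signs are arbitrary, so each component is
deterministically flipped to make its largest-magnitude score positive.
PCs are computed on the M scale (the replication cohort's documentation
does not state the scale; this is configurable by transforming first).

## Incremental association models

For each (trait, threshold) score, three nested logistic models of MDD
are fitted: model 1 with baseline covariates (discovery-style: age, sex;
replication-style: age, methylation PCs, cell proportions), model 2
adding the score's own phenotype, model 3 adding the lifestyle battery
(smoking status, pack years, alcohol units; duplicates are removed when
the trait itself is in the battery). Trait-validation models regress
each phenotype on its own score with the measurement-appropriate family:
linear, binary logistic, or proportional-odds cumulative-logit ordinal.
Complete cases are taken per model, not per suite, so model 3's sample
size shrinks when lifestyle covariates are missing — mirroring the real
analyses' shrinking model-3 N.

Variance explained is McFadden's pseudo-R², `1 − llf/ll0` against the
intercept-only model, with the **incremental** R² (full minus
score-dropped model) as the headline quantity; both full and incremental
values are emitted because published figures are ambiguous between them.
For the linear family the same ratio is formed from Gaussian
log-likelihoods (MLE variance), consistent with applying one pseudo-R²
across families. Nominal p-values are reported; no multiple-testing
correction is applied. Separation in a logistic fit (monotone
likelihood) raises an error rather than returning unstable estimates.
Sensitivity modes re-run models 2–3 within sex strata (sex dropped from
the covariates) and append smoking status to model 1 for all non-smoking
scores.

Two numerical facts the tests rely on: adding a predictor can never
lower a maximized likelihood, so incremental R² is non-negative up to
1e-10; and a proportional-odds fit with two outcome levels coincides
with binary logistic regression (verified to 1e-6, with the ordinal
optimizer's gradient tolerance tightened to make that hold).

## MDD methylation score (two-stage LASSO)

Stage 1 regresses 0/1 MDD status on covariates (age, sex, 10 genetic
PCs — accepted as phenotype columns; their computation is out of scope)
by ordinary least squares: the published wording implies continuous
residuals feeding a Gaussian penalized regression, so a linear
probability model is used rather than logistic residualization. Stage 2
fits an L1-penalized (elastic-net mixing 1) linear regression of those
residuals on all CpGs. The penalty is chosen by 10-fold
cross-validation at the minimum mean CV error; the 1-SE rule is
available behind a flag since the original rule is unstated. Folds are
stratified by case status (unstratified folds risk empty-case folds at
realistic prevalence) and seeded, making the fit bit-reproducible.
Train/test splitting follows a two-level set column when available
(mirroring the two DNAm release sets) or a seeded random fraction.

AUC is the Mann–Whitney probability with ties counted 1/2, computed via
midranks and verified against exhaustive pair enumeration. The DeLong
test uses the structural-components (placement-value) covariance
estimator; D is the standardized AUC difference with a two-sided normal
p. Identical score vectors return D = 0, p = 1; zero placement variance
with a nonzero AUC difference is an error.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor
`log ABF = 0.5 log(V/(V+W)) + (z²/2) · W/(V+W)` with `V = se²`,
`z = beta/se`, and prior effect variance `W`. Defaults follow the
conventional "default parameters": per-configuration priors
`p1 = p2 = 1e-4`, `p12 = 1e-5`, and prior effect SDs 0.2 for the
case-control trait and 0.15 for the quantitative (mQTL) trait — all
configurable. Hypothesis likelihoods aggregate single-causal
configurations in log space (log-sum-exp; H3 uses a stable
log-difference of the cross-product and shared terms), and posteriors
are prior-weighted and normalized. Per-SNP H4 posteriors are the
softmax of the summed per-trait log-ABFs. For regions of ≤ 6 SNPs the
implementation is checked against a direct probability-space enumeration
of every configuration to 1e-10.

Region extraction intersects the two panels within ±1 Mb of the index
SNP, aligns mQTL effect alleles to the GWAS (sign-flipping swapped
pairs), and drops strand-ambiguous A/T and C/G SNPs rather than
resolving them by frequency, since allele-frequency columns are
optional. One analysis is run per (region, CpG) pair where multiple
CpGs share a region. Evidence is classed **strong** when PP4 > 0.8 and
PP4/PP3 > 5, **suggestive** when PP4 > 0.5, else none; regions at
suggestive or better are looked up against the score recipes to name
the traits whose CpG sets contain the colocalized CpG. The
single-causal-variant-per-trait assumption is inherent to the method;
no conditioning or fine-mapping is attempted.

## Descriptive statistics

Categorical demographic rows are compared by the Pearson chi-square
without continuity correction — the published 2×2 sex statistic
(125.43) is the uncorrected value, verified arithmetically — and
continuous rows by the Welch unequal-variance t from group
mean/SD/N (the published fractional dfs such as 80.94 identify Welch).
Missing-data categories are included exactly where the published
degrees of freedom require it (replication-cohort smoking and alcohol)
and excluded where they require that (discovery-cohort smoking and
education); this is controlled by an explicit per-variable flag, never
inferred. All-zero categories are dropped before testing (the
replication education table needs this). Seven published statistics are
recomputed exactly from printed summaries; rows whose printed dfs imply
unprinted missingness (e.g. the discovery alcohol t) cannot be
recomputed from the table alone and are not asserted.

## Synthetic cohorts

The generator works on the M scale (beta obtained as `2^M/(2^M+1)`,
keeping beta strictly in (0,1)). A cohort is built as: per-CpG baseline
levels, Dirichlet cell proportions with loadings on ~20% of CpGs, batch
offsets on ~10%, and heteroscedastic noise. Each trait has a causal CpG
set with N(0,1) weights; the trait latent mixes the standardized true
CpG score with noise to hit a target variance explained in expectation.
Ordinal traits threshold the latent at equally spaced quantiles (the
category spacing of the real instruments is not modelled); binary traits
threshold at a prevalence. MDD is Bernoulli under a logistic liability
on the standardized trait latents, optionally plus a direct-methylation
pathway, with the intercept solved numerically for the target
prevalence. Smoking confounding is a latent binary exposure shifting a
CpG set that overlaps another trait's causal set — reproducing the
phenomenon where all of an education recipe's CpGs are also
smoking-associated.

Defaults mirror the study conditions: n = 9,502 samples, MDD prevalence
0.171 (1,626/9,502), six traits with variance-explained targets set to
the published score-on-trait pseudo-R² values (HDL 3.5%, total
cholesterol 1.4%, BMI 16.5%, education 1.25%, smoking 24.1%, alcohol
5.9%) and liability weights from the published per-trait logistic
associations with MDD. The default CpG count is 5,000 — a deliberate
desk-scale stand-in for the ~674k-probe array, since the scoring,
modelling, and colocalization mathematics are dimension-agnostic.
Simulated MWAS recipes add Gaussian estimation noise to the true
weights, with Wald p-values for causal CpGs and Uniform(0,1) p-values
for appended null CpGs (verified by a Kolmogorov–Smirnov check at
n = 5,000). Colocalization regions use AR(1)-correlated standardized
genotype variables, independent across the two studies, with causal
placement following the generating hypothesis.

What the generator does **not** emulate: realistic genome-wide LD,
pedigree/family structure, array probe chemistry and batch artefacts
beyond additive offsets, non-Gaussian methylation distributions, and
the real instruments' category frequencies. Passing tests therefore
demonstrate correctness of the statistical machinery and its
calibration under a plausible generative model — not transportability
of any effect-size estimate to the real cohorts, whose headline
coefficients require access-controlled data and are explicitly not
reproduced.

## Problem sizes and determinism

Test and verification runs use reduced dimensions chosen as the
package's own balance of statistical resolution and runtime:
enumeration checks on ≤ 6-SNP regions (100 fixtures), hypothesis
recovery on 50-SNP regions (100 per scenario, standardized effect 0.15,
GWAS n = 10,000, mQTL n = 5,000), coefficient recovery and type-I
calibration at n = 8,000 (50 and 1,000 replicates), mediation
attenuation at n = 3,000 (50 replicates), LASSO support recovery at
n = 2,000 with 1,000 CpGs (20 runs), and a 10,000-draw stratified paired
bootstrap for the DeLong cross-check. Every stochastic component takes
an explicit seed; fixed seeds give bit-identical matrices, phenotypes,
fold assignments, and pipeline artifact hashes.

## Known limitations

- Fixed-effects residualization cannot remove shared-family variance;
  on family-structured data the scores' standard errors would be
  anti-conservative.
- The linear-probability stage-1 residualization of the MDD score is a
  design reading of the published description, not a validated choice
  against it.
- McFadden R² values across different families are not strictly
  comparable; they are reported as given because the incremental
  difference within a family is the quantity of interest.
- Colocalization assumes at most one causal variant per trait per
  region; allelic heterogeneity deflates PP4.
- Strand-ambiguous SNPs are discarded, losing information where
  frequencies could have resolved them.
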