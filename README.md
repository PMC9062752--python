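# methscore

Methylation-score analysis of complex-trait risk factors for major
depressive disorder (MDD).

## The problem

Lifestyle and biochemical factors — smoking, alcohol consumption, BMI,
educational attainment, HDL and total cholesterol — leave reproducible
marks on blood DNA methylation, and several of them associate with MDD. A
**methylation score** (MS) summarizes a person's epigenetic signature of
such a trait as a weighted sum over trait-associated CpG sites,

```
MS_i = Σ_j  w_j · m_ij
```

with weights `w_j` taken from an external methylome-wide association study
(MWAS) and `m_ij` the methylation level (M-value) of CpG `j` in sample
`i`. Like a polygenic score, the CpG set can be restricted to
methylome-wide (Bonferroni) significance or relaxed to nested p-value
thresholds (0.01, 0.05, 0.1, 0.5).

This package implements, as a tested and reusable pipeline:

1. **Scoring** — MS construction from MWAS summary statistics at nested
   thresholds, with recipe/array overlap accounting.
2. **Association** — three incremental logistic models of MDD on each MS
   (baseline covariates; + the MS's own phenotype; + lifestyle battery),
   trait-validation models (linear / logistic / proportional-odds
   ordinal), and McFadden pseudo-R² accounting
   (`R²_incremental = R²_full − R²_without-MS`), plus sex-stratified and
   smoking-adjusted sensitivity analyses.
3. **MDD methylation score** — a two-stage LASSO: MDD status residualized
   on covariates, residuals regressed on all CpGs with an L1 penalty
   chosen by 10-fold cross-validation; evaluated by ROC AUC and the DeLong
   test for correlated ROC curves.
4. **Colocalization** — Wakefield approximate-Bayes-factor colocalization
   between an MDD GWAS and mQTL signals in ±1 Mb windows around index
   SNPs, with posteriors PP0–PP4 over the five single-causal-variant
   scenarios, the strong (PP4 > 0.8 and PP4/PP3 > 5) / suggestive
   (PP4 > 0.5) evidence rules, and look-up of colocalized CpGs in the MS
   recipes.
5. **Descriptive statistics** — case/control demographic tables with
   Pearson chi-square and Welch t tests, computable from published
   summary data alone.
6. **Synthetic data** — a cohort generator with known ground truth
   (cell-composition and batch structure, causal CpG sets with
   configurable variance explained, an MDD liability on the traits,
   smoking confounding of the methylome) so every stage is testable
   without access-controlled cohort data.

Individual-level data from the underlying population cohorts are
access-controlled and are **not** consumed; the pipeline runs end-to-end
on synthetic cohorts that emulate their structure.

## Worked example

```python
import methscore as ms

# a synthetic cohort mirroring the discovery cohort's structure
cfg = ms.gs_like_config(n_samples=2000, n_cpgs=1000, seed=1)
matrix, pheno, truth = ms.simulate_cohort(cfg)

# an MWAS recipe for smoking and scores at the five thresholds
mwas = ms.simulate_mwas(truth, "smoking", est_noise_sd=0.15,
                        n_null_cpgs=300, seed=2)
scores = ms.build_score_set(matrix, [mwas], standardize=True)

# model 1: MDD ~ age + sex + smoking MS (methylome-wide threshold)
d = pheno.table.join(scores.get("smoking", "MW").rename("_ms"))
res = ms.fit_glm(
    ms.ModelSpec("mdd", "binary-logistic", "_ms", ("age", "sex"), "model1"), d
)
print(f"beta={res.beta:.3f}  p={res.p_value:.2e}  "
      f"incremental R2={100 * res.incremental_r2:.2f}%")
```

Output:

```
beta=0.304  p=2.97e-07  incremental R2=1.41%
```

The MS coefficient is the log-odds of MDD per SD of the smoking score;
the incremental McFadden R² is the share of pseudo-variance the score
explains beyond age and sex. A colocalization region is analysed the same
way:

```python
gwas, mqtl, _ = ms.simulate_coloc_region("H4", n_snps=50, effect=0.15, seed=3)
region = ms.extract_region(gwas, mqtl, index_snp="rs25")
result = ms.coloc_abf(region)
print({k: round(v, 3) for k, v in result.pp.items()}, ms.classify_evidence(result))
```

```
{'PP0': 0.0, 'PP1': 0.0, 'PP2': 0.0, 'PP3': 0.0, 'PP4': 1.0} strong
```

A command-line interface wraps the same functions
(`methscore simulate|preprocess|score|associate|coloc|describe|run-all`);
`methscore run-all --seed 1 --out out/` executes the whole pipeline on a
synthetic cohort and writes inspectable TSVs plus a content-hash manifest.

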