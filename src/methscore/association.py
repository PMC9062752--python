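"""Incremental association models between methylation scores and outcomes.

Three nested logistic models relate each trait's methylation score (MS) to
MDD status: model 1 adjusts for baseline covariates only (e.g. age, sex),
model 2 adds the MS's own phenotype, and model 3 adds further lifestyle
covariates. Trait-validation models relate each MS to its own phenotype
(linear, logistic, or proportional-odds ordinal, depending on measurement).
The variance explained by the MS is reported as incremental McFadden
pseudo-R²: R²(full) − R²(model without the MS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .io import PhenotypeTable
from .scoring import ScoreSet

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "SuiteConfig",
    "fit_glm",
    "mcfadden_r2",
    "run_model_suite",
    "sensitivity_suite",
]

Family = Literal["binary-logistic", "linear", "ordinal-logistic"]


@dataclass(frozen=True)
class ModelSpec:
    """One regression: outcome ~ covariates + predictor (the MS)."""

    outcome: str
    family: Family
    predictor: str
    covariates: tuple[str, ...] = ()
    label: str = "model"

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError("predictor must not appear among covariates")


@dataclass
class AssociationResult:
    """MS coefficient and pseudo-R² accounting for one fitted model."""

    beta: float
    se: float
    p_value: float
    n_used: int
    mcfadden_r2_full: float
    mcfadden_r2_reduced: float
    incremental_r2: float
    family: Family
    label: str = "model"
    converged: bool = True
    loglik_full: float = float("nan")
    loglik_reduced: float = float("nan")
    loglik_null: float = float("nan")


def mcfadden_r2(loglik_full: float, loglik_null: float) -> float:
    """McFadden's pseudo-R²: 1 − ll_full / ll_null."""
    if loglik_null == 0.0:
        raise ValueError("degenerate outcome: null log-likelihood is zero")
    return 1.0 - loglik_full / loglik_null


def _expand_design(data: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """Numeric columns pass through; object/categorical expand to dummies."""
    parts = []
    for c in columns:
        s = data[c]
        if s.dtype.kind in "OUb" or isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(s, prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(s.astype(float).rename(c))
    if not parts:
        return pd.DataFrame(index=data.index)
    return pd.concat(parts, axis=1)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design (rank {rank} < {X.shape[1]}): {names}")


def _null_loglik(y: np.ndarray, family: Family) -> float:
    n = len(y)
    if family == "binary-logistic":
        p = y.mean()
        if p in (0.0, 1.0):
            raise ValueError("degenerate outcome: single class")
        return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))
    if family == "linear":
        var = float(np.var(y))  # MLE variance
        if var == 0:
            raise ValueError("degenerate outcome: zero variance")
        return float(-0.5 * n * (np.log(2 * np.pi * var) + 1.0))
    # ordinal: multinomial of category frequencies
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2:
        raise ValueError("degenerate outcome: single category")
    return float(np.sum(counts * np.log(counts / n)))


def _fit_family(
    y: np.ndarray, X: pd.DataFrame, family: Family
) -> tuple[float, pd.Series, pd.Series, pd.Series, bool]:
    """Fit one model; return (llf, params, bse, pvalues, converged).

    For the logistic and linear families an intercept is prepended; the
    ordinal family absorbs it into its thresholds.
    """
    if family == "binary-logistic":
        Xc = sm.add_constant(X.to_numpy(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ValueError(f"separation detected in logistic fit: {exc}") from exc
        mu = res.predict()
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            if np.abs(res.params).max() > 1e3:
                raise ValueError("separation detected: monotone likelihood")
        names = ["const", *X.columns]
        conv = bool(res.mle_retvals.get("converged", True))
        return (
            float(res.llf),
            pd.Series(res.params, index=names),
            pd.Series(res.bse, index=names),
            pd.Series(res.pvalues, index=names),
            conv,
        )
    if family == "linear":
        Xc = sm.add_constant(X.to_numpy(float), has_constant="add")
        _check_rank(Xc, ["const", *X.columns])
        res = sm.OLS(y, Xc).fit()
        names = ["const", *X.columns]
        return (
            float(res.llf),
            pd.Series(res.params, index=names),
            pd.Series(res.bse, index=names),
            pd.Series(res.pvalues, index=names),
            True,
        )
    # ordinal-logistic: proportional-odds cumulative logit
    if X.shape[1] == 0:
        raise ValueError("ordinal null fits are computed analytically")
    endog = pd.Series(y).astype("category").cat.as_ordered()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = OrderedModel(endog, X.to_numpy(float), distr="logit").fit(
            method="bfgs", disp=0, maxiter=500, gtol=1e-10
        )
    k = X.shape[1]
    names = list(X.columns)
    conv = bool(res.mle_retvals.get("converged", True))
    return (
        float(res.llf),
        pd.Series(np.asarray(res.params)[:k], index=names),
        pd.Series(np.asarray(res.bse)[:k], index=names),
        pd.Series(np.asarray(res.pvalues)[:k], index=names),
        conv,
    )


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """Maximum-likelihood fit of outcome ~ covariates + MS, complete cases.

    Returns the MS coefficient with its Wald SE and p-value, plus McFadden
    pseudo-R² for the full model and for the model with the MS dropped
    (both against the intercept-only null); their difference is the
    incremental R² attributable to the MS.
    """
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"column {c!r} not in data")
    sub = data[cols].dropna()
    n_used = len(sub)
    y = sub[spec.outcome].to_numpy()
    if spec.family == "binary-logistic":
        y = y.astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binary outcome must be 0/1")
    elif spec.family == "linear":
        y = y.astype(float)
    else:
        levels = np.unique(y)
        if len(levels) < 2:
            raise ValueError("ordinal outcome needs >= 2 observed levels")

    X_cov = _expand_design(sub, spec.covariates)
    X_full = pd.concat([X_cov, sub[spec.predictor].astype(float)], axis=1)
    n_params = X_full.shape[1] + (2 if spec.family != "linear" else 2)
    if n_used <= n_params:
        raise ValueError(f"too few complete cases (n={n_used}) for {n_params} parameters")
    _check_rank(
        np.column_stack([np.ones(n_used), X_full.to_numpy(float)]),
        ["const", *X_full.columns],
    )

    ll_null = _null_loglik(y, spec.family)
    ll_full, params, bse, pvals, conv = _fit_family(y, X_full, spec.family)
    if X_cov.shape[1] > 0:
        ll_red, *_ = _fit_family(y, X_cov, spec.family)
    else:
        ll_red = ll_null
    r2_full = mcfadden_r2(ll_full, ll_null)
    r2_red = mcfadden_r2(ll_red, ll_null)
    return AssociationResult(
        beta=float(params[spec.predictor]),
        se=float(bse[spec.predictor]),
        p_value=float(pvals[spec.predictor]),
        n_used=n_used,
        mcfadden_r2_full=r2_full,
        mcfadden_r2_reduced=r2_red,
        incremental_r2=r2_full - r2_red,
        family=spec.family,
        label=spec.label,
        converged=conv,
        loglik_full=ll_full,
        loglik_reduced=ll_red,
        loglik_null=ll_null,
    )


@dataclass
class SuiteConfig:
    """Column wiring for the incremental model suite.

    ``trait_phenotypes`` maps each scored trait to its phenotype column and
    measurement family (for the trait-validation model and for the model-2
    own-phenotype adjustment). ``base_covariates`` are the model-1
    covariates (GS-style: age, sex; ALSPAC-style: age + methylation PCs +
    cell proportions); ``lifestyle_covariates`` are added in model 3.
    """

    mdd_col: str = "mdd"
    base_covariates: tuple[str, ...] = ("age", "sex")
    lifestyle_covariates: tuple[str, ...] = ("smoking_status", "pack_years", "alcohol_units")
    trait_phenotypes: dict[str, tuple[str, Family]] = field(default_factory=dict)
    smoking_trait: str | None = "smoking_status"
    smoking_covariate: str = "smoking_status"


def _dedupe(seq: tuple[str, ...]) -> tuple[str, ...]:
    out: list[str] = []
    for c in seq:
        if c not in out:
            out.append(c)
    return tuple(out)


def _ms_column(data: pd.DataFrame, scores: ScoreSet, trait: str, th: str) -> pd.DataFrame:
    s = scores.get(trait, th).rename("_ms")
    return data.join(s)


def run_model_suite(
    pheno: PhenotypeTable, scores: ScoreSet, config: SuiteConfig
) -> pd.DataFrame:
    """Models 1–3 plus trait validation for every (trait, threshold) score.

    Complete cases are taken per model, not per suite, so model 3's n can
    shrink relative to models 1–2.
    """
    rows = []
    data = pheno.table
    for trait in scores.traits():
        if trait not in config.trait_phenotypes:
            raise KeyError(f"no phenotype configured for trait {trait!r}")
        ph_col, ph_family = config.trait_phenotypes[trait]
        for th in scores.thresholds_for(trait):
            d = _ms_column(data, scores, trait, th)
            covs1 = _dedupe(config.base_covariates)
            covs2 = _dedupe((*covs1, ph_col))
            covs3 = _dedupe((*covs2, *config.lifestyle_covariates))
            specs = [
                ModelSpec(config.mdd_col, "binary-logistic", "_ms", covs1, "model1"),
                ModelSpec(config.mdd_col, "binary-logistic", "_ms", covs2, "model2"),
                ModelSpec(config.mdd_col, "binary-logistic", "_ms", covs3, "model3"),
                ModelSpec(ph_col, ph_family, "_ms", covs1, "trait_validation"),
            ]
            for spec in specs:
                res = fit_glm(spec, d)
                rows.append(
                    {
                        "trait": trait,
                        "threshold": th,
                        "model": spec.label,
                        "beta": res.beta,
                        "se": res.se,
                        "p": res.p_value,
                        "n": res.n_used,
                        "r2_full": res.mcfadden_r2_full,
                        "r2_reduced": res.mcfadden_r2_reduced,
                        "r2_incremental": res.incremental_r2,
                        "family": res.family,
                    }
                )
    return pd.DataFrame(rows)


def sensitivity_suite(
    pheno: PhenotypeTable,
    scores: ScoreSet,
    mode: Literal["sex_stratified", "smoking_adjusted_model1"],
    config: SuiteConfig,
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Sensitivity analyses around the main suite.

    ``sex_stratified`` re-runs models 2 and 3 within each sex stratum with
    the sex covariate dropped. ``smoking_adjusted_model1`` appends smoking
    status to the model-1 covariates for every non-smoking MS (the smoking
    MS rows are re-emitted unchanged).
    """
    rows = []
    data = pheno.table
    if mode == "sex_stratified":
        if sex_col not in data.columns:
            raise KeyError(f"sex column {sex_col!r} absent")
        for stratum in sorted(data[sex_col].dropna().unique()):
            sub = data[data[sex_col] == stratum]
            n_cases = int(sub[config.mdd_col].sum())
            if n_cases == 0 or n_cases == sub[config.mdd_col].notna().sum():
                raise ValueError(f"stratum {stratum!r} has zero cases or zero controls")
            sub_pheno = PhenotypeTable(sub, pheno.cell_columns, pheno.pc_columns)
            for trait in scores.traits():
                ph_col, _ = config.trait_phenotypes[trait]
                base = tuple(c for c in config.base_covariates if c != sex_col)
                for th in scores.thresholds_for(trait):
                    d = _ms_column(sub, scores, trait, th)
                    covs2 = _dedupe((*base, ph_col))
                    covs3 = _dedupe((*covs2, *config.lifestyle_covariates))
                    for covs, label in ((covs2, "model2"), (covs3, "model3")):
                        spec = ModelSpec(config.mdd_col, "binary-logistic", "_ms", covs, label)
                        res = fit_glm(spec, d)
                        rows.append(
                            {
                                "trait": trait,
                                "threshold": th,
                                "model": label,
                                "stratum": stratum,
                                "beta": res.beta,
                                "se": res.se,
                                "p": res.p_value,
                                "n": res.n_used,
                                "r2_incremental": res.incremental_r2,
                            }
                        )
        return pd.DataFrame(rows)

    if mode == "smoking_adjusted_model1":
        for trait in scores.traits():
            base = _dedupe(config.base_covariates)
            if trait != config.smoking_trait:
                covs = _dedupe((*base, config.smoking_covariate))
            else:
                covs = base
            for th in scores.thresholds_for(trait):
                d = _ms_column(data, scores, trait, th)
                spec = ModelSpec(config.mdd_col, "binary-logistic", "_ms", covs, "model1_smoking_adj")
                res = fit_glm(spec, d)
                rows.append(
                    {
                        "trait": trait,
                        "threshold": th,
                        "model": spec.label,
                        "smoking_adjusted": trait != config.smoking_trait,
                        "beta": res.beta,
                        "se": res.se,
                        "p": res.p_value,
                        "n": res.n_used,
                        "r2_incremental": res.incremental_r2,
                    }
                )
        return pd.DataFrame(rows)

    raise ValueError(f"unknown sensitivity mode {mode!r}")
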