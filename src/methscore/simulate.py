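"""Synthetic cohorts, MWAS weights, and colocalization regions.

Every downstream stage of the pipeline is exercised on data generated here
with known ground truth, emulating the statistical structure of a
population DNAm cohort: an M-scale methylation matrix with cell-composition
and batch structure, lifestyle/biochemical traits driven by causal CpG
sets at a configurable variance explained, an MDD liability built from
those traits (optionally with direct methylation effects), and a latent
smoking exposure that perturbs a CpG set shared with another trait's
causal set to reproduce smoking confounding of methylation scores.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import AssocSummaryStats, MethylationMatrix, MwasSummary, PhenotypeTable

__all__ = [
    "TraitConfig",
    "MddModel",
    "SmokingConfounding",
    "CohortConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_mwas",
    "simulate_coloc_region",
    "gs_like_config",
]


@dataclass(frozen=True)
class TraitConfig:
    """One simulated trait driven by a causal CpG set.

    ``target_r2`` is the variance in the trait's latent explained by its
    true CpG score, in expectation. Ordinal traits threshold the latent at
    equally spaced quantiles into ``n_levels`` categories.
    """

    name: str
    n_causal_cpgs: int
    target_r2: float
    measurement: Literal["continuous", "binary", "ordinal"] = "continuous"
    n_levels: int = 4
    binary_prevalence: float = 0.5


@dataclass(frozen=True)
class MddModel:
    """Logistic liability for MDD on the standardized trait latents.

    ``trait_weights`` are log-odds per SD of each trait latent;
    ``direct_weight`` adds a direct methylation pathway via a random CpG
    set. The intercept is solved so the expected case fraction equals
    ``prevalence``.
    """

    prevalence: float = 0.171
    trait_weights: dict[str, float] = field(default_factory=dict)
    direct_weight: float = 0.0
    n_direct_cpgs: int = 20
    noise_sd: float = 0.0  # extra liability noise beyond the Bernoulli draw


@dataclass(frozen=True)
class SmokingConfounding:
    """Latent binary smoking exposure perturbing the methylome.

    ``n_affected_cpgs`` CpGs shift by ``effect_size`` (M-scale) in exposed
    samples; ``n_shared_with`` of them are drawn from ``shared_trait``'s
    causal set, reproducing the overlap between smoking- and
    education-associated CpGs.
    """

    exposure_prevalence: float = 0.3
    effect_size: float = 0.0
    n_affected_cpgs: int = 0
    shared_trait: str | None = None
    n_shared_with: int = 0


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 9502
    n_cpgs: int = 5000
    traits: tuple[TraitConfig, ...] = ()
    mdd: MddModel = field(default_factory=MddModel)
    confounding: SmokingConfounding = field(default_factory=SmokingConfounding)
    n_cell_types: int = 5
    n_batches: int = 2
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mdd.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        for t in self.traits:
            if not (0 < t.target_r2 < 1):
                raise ValueError(f"target_r2 for {t.name} must be in (0, 1)")
            if t.n_causal_cpgs > self.n_cpgs:
                raise ValueError(f"{t.name}: n_causal_cpgs exceeds n_cpgs")
            if t.n_causal_cpgs < 1:
                raise ValueError(f"{t.name}: need at least one causal CpG")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    cpg_ids: list[str]
    causal_cpgs: dict[str, list[str]]
    true_weights: dict[str, np.ndarray]
    trait_latents: dict[str, np.ndarray]
    liability_intercept: float
    liability_weights: dict[str, float]
    direct_cpgs: list[str]
    direct_cpg_weights: np.ndarray | None
    smoking_exposed: np.ndarray | None
    smoking_cpgs: list[str]
    cell_loadings: np.ndarray
    batch_loadings: np.ndarray
    seed: int


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate latent: zero variance")
    return (x - x.mean()) / sd


def _ordinalize(latent: np.ndarray, n_levels: int) -> np.ndarray:
    """Threshold a latent at equally spaced quantiles into 0..n_levels-1."""
    qs = np.quantile(latent, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(qs, latent, side="left").astype(float)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[MethylationMatrix, PhenotypeTable, SimTruth]:
    """Generate one cohort: M-scale matrix, phenotypes, and ground truth."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_cpgs
    cpg_ids = [f"cg{i:08d}" for i in range(p)]
    sample_ids = [f"S{i:06d}" for i in range(n)]

    # structural components: cell composition + batch + noise
    cells = rng.dirichlet(np.full(config.n_cell_types, 5.0), size=n)
    cell_load = np.zeros((config.n_cell_types, p))
    n_cell_cpgs = max(1, p // 5)
    cell_idx = rng.choice(p, size=n_cell_cpgs, replace=False)
    cell_load[:, cell_idx] = rng.normal(0, 1.5, size=(config.n_cell_types, n_cell_cpgs))
    batch = rng.integers(0, config.n_batches, size=n)
    batch_load = np.zeros((config.n_batches, p))
    n_batch_cpgs = max(1, p // 10)
    batch_idx = rng.choice(p, size=n_batch_cpgs, replace=False)
    batch_load[:, batch_idx] = rng.normal(0, 0.3, size=(config.n_batches, n_batch_cpgs))

    mu = rng.normal(0.0, 2.0, size=p)
    noise_sd = rng.uniform(0.5, 1.5, size=p)
    M = (
        mu
        + cells @ cell_load
        + batch_load[batch]
        + rng.normal(0, 1, size=(n, p)) * noise_sd
    )

    # causal CpG sets and true weights per trait
    causal: dict[str, list[str]] = {}
    weights: dict[str, np.ndarray] = {}
    causal_idx: dict[str, np.ndarray] = {}
    for t in config.traits:
        idx = rng.choice(p, size=t.n_causal_cpgs, replace=False)
        causal_idx[t.name] = idx
        causal[t.name] = [cpg_ids[i] for i in idx]
        weights[t.name] = rng.normal(0, 1, size=t.n_causal_cpgs)

    # smoking exposure perturbs the methylome before traits are read off it
    conf = config.confounding
    exposed: np.ndarray | None = None
    smoking_cpgs: list[str] = []
    if conf.effect_size != 0.0 and conf.n_affected_cpgs > 0:
        exposed = (rng.random(n) < conf.exposure_prevalence).astype(float)
        affected: list[int] = []
        if conf.shared_trait is not None and conf.n_shared_with > 0:
            shared_pool = causal_idx[conf.shared_trait]
            k = min(conf.n_shared_with, len(shared_pool))
            affected.extend(rng.choice(shared_pool, size=k, replace=False).tolist())
        n_rest = conf.n_affected_cpgs - len(affected)
        if n_rest > 0:
            pool = np.setdiff1d(np.arange(p), np.array(affected, int))
            affected.extend(rng.choice(pool, size=n_rest, replace=False).tolist())
        aff = np.array(affected, int)
        M[:, aff] += exposed[:, None] * conf.effect_size
        smoking_cpgs = [cpg_ids[i] for i in aff]

    # traits from their causal CpGs, scaled to hit target_r2 in expectation
    latents: dict[str, np.ndarray] = {}
    pheno = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for t in config.traits:
        g = M[:, causal_idx[t.name]] @ weights[t.name]
        z = _standardize(g)
        lat = np.sqrt(t.target_r2) * z + np.sqrt(1 - t.target_r2) * rng.normal(0, 1, n)
        latents[t.name] = lat
        if t.measurement == "continuous":
            pheno[t.name] = lat
        elif t.measurement == "binary":
            cut = np.quantile(lat, 1 - t.binary_prevalence)
            pheno[t.name] = (lat > cut).astype(float)
        else:
            pheno[t.name] = _ordinalize(lat, t.n_levels)

    # MDD from a logistic liability on standardized trait latents
    mdd = config.mdd
    liab = np.zeros(n)
    for name, w in mdd.trait_weights.items():
        if name not in latents:
            raise ValueError(f"liability weight for unknown trait {name!r}")
        liab += w * _standardize(latents[name])
    direct_cpgs: list[str] = []
    direct_w: np.ndarray | None = None
    if mdd.direct_weight != 0.0 and mdd.n_direct_cpgs > 0:
        didx = rng.choice(p, size=mdd.n_direct_cpgs, replace=False)
        direct_cpgs = [cpg_ids[i] for i in didx]
        direct_w = rng.normal(0, 1, size=mdd.n_direct_cpgs)
        dscore = M[:, didx] @ direct_w
        liab += mdd.direct_weight * _standardize(dscore)
    if mdd.noise_sd > 0:
        liab += rng.normal(0, mdd.noise_sd, n)

    def case_gap(alpha: float) -> float:
        return expit(alpha + liab).mean() - mdd.prevalence

    alpha = brentq(case_gap, -30.0, 30.0)
    pheno.insert(0, "mdd", (rng.random(n) < expit(alpha + liab)).astype(float))

    # demographics and technical columns
    pheno["age"] = np.clip(rng.normal(50, 13, n), 18, 98).round(1)
    pheno["sex"] = np.where(rng.random(n) < 0.59, "F", "M")
    if exposed is not None:
        base = np.where(exposed == 1, 2.2, 0.4) + rng.normal(0, 0.8, n)
        pheno["smoking_status"] = np.clip(np.round(base), 0, 3)
        pheno["pack_years"] = np.round(
            exposed * rng.gamma(2.0, 8.0, n) + (1 - exposed) * rng.gamma(1.1, 0.5, n), 1
        )
    for i in range(config.n_cell_types):
        pheno[f"cell_{i + 1}"] = cells[:, i]
    for i in range(config.n_pcs):
        pheno[f"pc{i + 1}"] = rng.normal(0, 1, n)
    pheno["batch"] = batch
    pheno["set_label"] = np.where(rng.random(n) < 0.535, 1, 2)

    matrix = MethylationMatrix(
        pd.DataFrame(M, index=pheno.index, columns=cpg_ids), "m"
    )
    truth = SimTruth(
        cpg_ids=cpg_ids,
        causal_cpgs=causal,
        true_weights=weights,
        trait_latents=latents,
        liability_intercept=float(alpha),
        liability_weights=dict(mdd.trait_weights),
        direct_cpgs=direct_cpgs,
        direct_cpg_weights=direct_w,
        smoking_exposed=exposed,
        smoking_cpgs=smoking_cpgs,
        cell_loadings=cell_load,
        batch_loadings=batch_load,
        seed=config.seed,
    )
    cell_cols = tuple(f"cell_{i + 1}" for i in range(config.n_cell_types))
    pc_cols = tuple(f"pc{i + 1}" for i in range(config.n_pcs))
    return matrix, PhenotypeTable(pheno, cell_cols, pc_cols), truth


def simulate_mwas(
    truth: SimTruth,
    trait: str,
    est_noise_sd: float = 0.0,
    n_null_cpgs: int = 0,
    seed: int = 0,
) -> MwasSummary:
    """A training MWAS for one simulated trait.

    Causal CpGs get their true weight plus estimation noise and a small
    p-value (the Wald p implied by the noise level); appended null CpGs,
    drawn from the cohort's non-causal probes, get noise-only weights and
    Uniform(0,1) p-values.
    """
    from scipy import stats as _st

    if trait not in truth.causal_cpgs:
        raise KeyError(f"unknown trait {trait!r}")
    if est_noise_sd < 0:
        raise ValueError("est_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cpgs = list(truth.causal_cpgs[trait])
    w_true = truth.true_weights[trait]
    if est_noise_sd > 0:
        w_est = w_true + rng.normal(0, est_noise_sd, len(w_true))
        p_causal = 2 * _st.norm.sf(np.abs(w_est) / est_noise_sd)
        p_causal = np.clip(p_causal, 1e-300, 1.0)
    else:
        w_est = w_true.copy()
        p_causal = np.full(len(w_true), 1e-20)
    rows = pd.DataFrame({"cpg": cpgs, "weight": w_est, "p": p_causal})
    if n_null_cpgs > 0:
        pool = [c for c in truth.cpg_ids if c not in set(cpgs)]
        if n_null_cpgs > len(pool):
            raise ValueError("not enough non-causal CpGs for requested nulls")
        null_ids = [pool[i] for i in rng.choice(len(pool), n_null_cpgs, replace=False)]
        null_w = rng.normal(0, est_noise_sd if est_noise_sd > 0 else 0.05, n_null_cpgs)
        null_p = rng.uniform(0, 1, n_null_cpgs)
        rows = pd.concat(
            [rows, pd.DataFrame({"cpg": null_ids, "weight": null_w, "p": null_p})],
            ignore_index=True,
        )
    return MwasSummary(trait_name=trait, table=rows)


def _marginal_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple-regression beta and SE (vectorized)."""
    n = len(y)
    xm = X - X.mean(axis=0)
    ym = y - y.mean()
    sxx = (xm**2).sum(axis=0)
    beta = (xm * ym[:, None]).sum(axis=0) / sxx
    resid_ss = (ym**2).sum() - beta**2 * sxx
    se = np.sqrt(np.maximum(resid_ss, 1e-12) / ((n - 2) * sxx))
    return beta, se


def simulate_coloc_region(
    hypothesis: Literal["H0", "H1", "H2", "H3", "H4"],
    n_snps: int = 50,
    n1: int = 10000,
    n2: int = 5000,
    effect: float = 0.1,
    ld: float = 0.5,
    seed: int = 0,
) -> tuple[AssocSummaryStats, AssocSummaryStats, dict[str, int | None]]:
    """Summary statistics for two traits in one region under H0–H4.

    Standardized genotype-like variables with AR(1) correlation ``ld`` are
    drawn independently for the two studies; causal placement follows the
    hypothesis (none / trait 1 only / trait 2 only / two distinct / one
    shared). ``effect`` is the standardized per-allele effect.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if hypothesis == "H3" and n_snps < 2:
        raise ValueError("H3 needs at least 2 SNPs")
    if hypothesis != "H0" and effect <= 0:
        raise ValueError("effect must be positive for non-H0 hypotheses")
    if not (0 <= ld < 1):
        raise ValueError("ld must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def draw_genotypes(n: int) -> np.ndarray:
        # AR(1) via sequential construction on standard normals
        Z = rng.normal(0, 1, size=(n, n_snps))
        X = np.empty_like(Z)
        X[:, 0] = Z[:, 0]
        for j in range(1, n_snps):
            X[:, j] = ld * X[:, j - 1] + np.sqrt(1 - ld**2) * Z[:, j]
        return X

    c1: int | None = None
    c2: int | None = None
    if hypothesis == "H1":
        c1 = int(rng.integers(n_snps))
    elif hypothesis == "H2":
        c2 = int(rng.integers(n_snps))
    elif hypothesis == "H3":
        c1, c2 = rng.choice(n_snps, size=2, replace=False).tolist()
    elif hypothesis == "H4":
        c1 = c2 = int(rng.integers(n_snps))

    X1 = draw_genotypes(n1)
    X2 = draw_genotypes(n2)
    y1 = rng.normal(0, 1, n1) + (effect * X1[:, c1] if c1 is not None else 0.0)
    y2 = rng.normal(0, 1, n2) + (effect * X2[:, c2] if c2 is not None else 0.0)
    b1, se1 = _marginal_stats(X1, y1)
    b2, se2 = _marginal_stats(X2, y2)

    snps = [f"rs{i + 1}" for i in range(n_snps)]
    pos = [1_000_000 + 1000 * i for i in range(n_snps)]
    common = {"chr": "1", "ea": "A", "oa": "G"}
    gwas = AssocSummaryStats(
        pd.DataFrame(
            {"snp": snps, "pos": pos, "beta": b1, "se": se1, "n": n1, **common}
        )[["snp", "chr", "pos", "ea", "oa", "beta", "se", "n"]],
        "gwas",
    )
    mqtl = AssocSummaryStats(
        pd.DataFrame(
            {
                "snp": snps,
                "pos": pos,
                "beta": b2,
                "se": se2,
                "n": n2,
                "cpg": "cg00000001",
                **common,
            }
        )[["snp", "chr", "pos", "ea", "oa", "beta", "se", "n", "cpg"]],
        "mqtl",
    )
    return gwas, mqtl, {"gwas": c1, "mqtl": c2}


def gs_like_config(
    n_samples: int = 9502,
    n_cpgs: int = 5000,
    seed: int = 0,
    *,
    confounded: bool = True,
) -> CohortConfig:
    """Default cohort mirroring the study's structure at desk scale.

    Six traits with per-trait variance explained set to the validated
    score-on-trait pseudo-R² values (HDL 3.5%, total cholesterol 1.4%, BMI
    16.5%, education 1.25%, smoking 24.1%, alcohol 5.9%); MDD prevalence
    0.171 (1626/9502) with liability weights taken from the reported
    per-trait logistic associations with MDD.
    """
    traits = (
        TraitConfig("hdl", 25, 0.035),
        TraitConfig("tchol", 25, 0.014),
        TraitConfig("bmi", 40, 0.165),
        TraitConfig("education", 11, 0.0125, "ordinal", n_levels=9),
        TraitConfig("smoking", 60, 0.241, "ordinal", n_levels=4),
        TraitConfig("alcohol_units", 30, 0.059),
    )
    mdd = MddModel(
        prevalence=0.171,
        trait_weights={
            "hdl": -0.116,
            "tchol": 0.069,
            "bmi": 0.149,
            "education": -0.003,
            "smoking": 0.567,
            "alcohol_units": 0.103,
        },
    )
    conf = SmokingConfounding(
        exposure_prevalence=0.3,
        effect_size=0.8 if confounded else 0.0,
        n_affected_cpgs=80 if confounded else 0,
        shared_trait="education",
        n_shared_with=11 if confounded else 0,
    )
    return CohortConfig(
        n_samples=n_samples,
        n_cpgs=n_cpgs,
        traits=traits,
        mdd=mdd,
        confounding=conf,
        seed=seed,
    )
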