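"""End-to-end orchestration: simulate -> preprocess -> score -> associate ->
MDD score -> colocalize -> describe, from one YAML config.

Every stage writes plain TSV so intermediates are inspectable; the run
manifest records a content hash per output, and an identical config+seed
reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .association import SuiteConfig, run_model_suite
from .coloc import classify_evidence, coloc_abf, extract_region, lookup_ms_cpgs
from .descriptive import demographics_table
from .io import write_methylation_matrix, write_mwas_summary, write_phenotypes
from .mdd import delong_test, roc_auc, split_cohort, train_penalized_score
from .preprocess import methylation_pcs, residualize
from .scoring import DEFAULT_THRESHOLDS, ThresholdSpec, build_score_set
from .simulate import gs_like_config, simulate_coloc_region, simulate_mwas, simulate_cohort

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_ALLOWED_THRESHOLDS = {"MW", "0.01", "0.05", "0.1", "0.5"}


@dataclass
class RunConfig:
    """Parsed run configuration. See ``validate_config`` for constraints."""

    seed: int = 0
    out_dir: str = "out"
    n_samples: int = 2000
    n_cpgs: int = 1000
    thresholds: tuple[str, ...] = ("MW", "0.01", "0.05", "0.1", "0.5")
    mwas_noise_sd: float = 0.15
    mwas_null_cpgs: int = 300
    base_covariates: tuple[str, ...] = ("age", "sex")
    lifestyle_covariates: tuple[str, ...] = ("smoking", "pack_years", "alcohol_units")
    mdd_folds: int = 5
    coloc_hypotheses: tuple[str, ...] = ("H0", "H1", "H4")
    n_pcs: int = 0
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {"raw": raw}
        for key in (
            "seed",
            "out_dir",
            "n_samples",
            "n_cpgs",
            "mwas_noise_sd",
            "mwas_null_cpgs",
            "mdd_folds",
            "n_pcs",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("thresholds", "base_covariates", "lifestyle_covariates", "coloc_hypotheses"):
            if key in raw:
                kwargs[key] = tuple(str(x) for x in raw[key])
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Empty list iff the config is runnable; each problem names its key."""
    problems = []
    if not isinstance(config.seed, (int, np.integer)) or isinstance(config.seed, bool):
        problems.append("seed: must be an integer")
    elif config.seed < 0:
        problems.append("seed: must be non-negative")
    for th in config.thresholds:
        if th not in _ALLOWED_THRESHOLDS:
            problems.append(f"thresholds: {th!r} not in declared set {sorted(_ALLOWED_THRESHOLDS)}")
    if config.n_samples < 100:
        problems.append("n_samples: too small for the model suite (need >= 100)")
    if config.n_cpgs < 50:
        problems.append("n_cpgs: need at least 50")
    if config.mdd_folds < 2:
        problems.append("mdd_folds: need at least 2 folds")
    for h in config.coloc_hypotheses:
        if h not in {"H0", "H1", "H2", "H3", "H4"}:
            problems.append(f"coloc_hypotheses: unknown hypothesis {h!r}")
    for key in ("matrix", "phenotypes"):
        path = config.raw.get("inputs", {}).get(key)
        if path is not None and not Path(path).exists():
            problems.append(f"inputs.{key}: file {path!r} does not exist")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _threshold_specs(labels: tuple[str, ...]) -> tuple[ThresholdSpec, ...]:
    by_label = {t.label: t for t in DEFAULT_THRESHOLDS}
    return tuple(by_label[l] for l in labels)


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute all stages in dependency order; return the artifact manifest.

    The manifest maps each output file (relative to ``out_dir``) to its
    SHA-256 content hash.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate
    cohort_cfg = gs_like_config(config.n_samples, config.n_cpgs, seed=config.seed)
    matrix, pheno, truth = simulate_cohort(cohort_cfg)
    write_methylation_matrix(matrix, out / "matrix.tsv")
    write_phenotypes(pheno, out / "phenotypes.tsv")

    # --- preprocess: optional methylation PCs on residualized data
    if config.n_pcs > 0:
        resid = residualize(matrix, pheno, ["age", "sex"])
        pcs = methylation_pcs(resid, config.n_pcs)
        pcs.to_csv(out / "methylation_pcs.tsv", sep="\t", index_label="sample_id")

    # --- MWAS recipes and scores
    recipes = []
    for i, trait_cfg in enumerate(cohort_cfg.traits):
        mwas = simulate_mwas(
            truth,
            trait_cfg.name,
            est_noise_sd=config.mwas_noise_sd,
            n_null_cpgs=config.mwas_null_cpgs,
            seed=config.seed + 101 + i,
        )
        write_mwas_summary(mwas, out / f"mwas_{trait_cfg.name}.tsv")
        recipes.append(mwas)
    scores = build_score_set(
        matrix, recipes, _threshold_specs(config.thresholds), standardize=True
    )
    scores.to_frame().to_csv(out / "scores.tsv", sep="\t", index=False)

    # --- association suite
    families = {t.name: ("ordinal-logistic" if t.measurement == "ordinal" else "linear")
                for t in cohort_cfg.traits}
    suite = SuiteConfig(
        mdd_col="mdd",
        base_covariates=config.base_covariates,
        lifestyle_covariates=config.lifestyle_covariates,
        trait_phenotypes={name: (name, families[name]) for name in families},
        smoking_trait="smoking",
        smoking_covariate="smoking",
    )
    results = run_model_suite(pheno, scores, suite)
    results.to_csv(out / "associations.tsv", sep="\t", index=False)

    # --- MDD methylation score: train/test split by set, LASSO, ROC/DeLong
    train_ids, test_ids = split_cohort(pheno, by="set_label")
    from .io import MethylationMatrix, PhenotypeTable  # local alias

    m_train = MethylationMatrix(matrix.values.loc[train_ids], matrix.scale)
    m_test = MethylationMatrix(matrix.values.loc[test_ids], matrix.scale)
    p_train = PhenotypeTable(pheno.table.loc[train_ids], pheno.cell_columns, pheno.pc_columns)
    covs = ["age", "sex"] + [f"pc{i + 1}" for i in range(10)]
    model = train_penalized_score(m_train, p_train, covs, folds=config.mdd_folds, seed=config.seed)
    mdd_scores = model.predict(m_test)
    labels = pheno.table.loc[test_ids, "mdd"].to_numpy(float)
    roc_rows = [
        {
            "score_name": "mdd_ms",
            "auc": roc_auc(mdd_scores, labels),
            "delong_D_vs_mdd_ms": 0.0,
            "p": 1.0,
            "n_selected_cpgs": len(model.selected_cpgs_),
        }
    ]
    for trait in scores.traits():
        th0 = scores.thresholds_for(trait)[0]
        ts = scores.get(trait, th0).loc[test_ids]
        cmp_res = delong_test(ts, mdd_scores, labels)
        roc_rows.append(
            {
                "score_name": f"{trait}_{th0}",
                "auc": cmp_res.auc_a,
                "delong_D_vs_mdd_ms": cmp_res.delong_d,
                "p": cmp_res.p_value,
                "n_selected_cpgs": scores.reports[(trait, th0)].n_used,
            }
        )
    pd.DataFrame(roc_rows).to_csv(out / "roc.tsv", sep="\t", index=False)

    # --- colocalization on simulated regions
    coloc_rows = []
    results_list = []
    for i, hyp in enumerate(config.coloc_hypotheses):
        gwas, mqtl, _ = simulate_coloc_region(
            hyp, n_snps=50, effect=0.12, seed=config.seed + 201 + i
        )
        region = extract_region(gwas, mqtl, index_snp="rs25")
        res = coloc_abf(region)
        tier = classify_evidence(res)
        results_list.append(res)
        coloc_rows.append(
            {
                "index_snp": region.index_snp,
                "generating_hypothesis": hyp,
                "n_snps": res.n_snps,
                **res.pp,
                "tier": tier,
                "top_snp": res.top_snp,
                "top_snp_posterior": res.top_snp_posterior,
            }
        )
    pd.DataFrame(coloc_rows).to_csv(out / "coloc.tsv", sep="\t", index=False)
    lookup = lookup_ms_cpgs(results_list, recipes)
    lookup.to_csv(out / "coloc_ms_lookup.tsv", sep="\t", index=False)

    # --- demographics
    demo = demographics_table(
        pheno,
        "mdd",
        continuous=("age", "bmi", "hdl", "alcohol_units"),
        categorical=("sex", "smoking"),
    )
    demo.to_csv(out / "demographics.tsv", sep="\t", index=False)

    manifest = {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
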