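"""Approximate-Bayes-factor colocalization between two association signals.

Given per-SNP summary statistics for two traits in a genomic window (here:
an MDD GWAS and a GoDMC-style mQTL), the method asks which of five
mutually exclusive scenarios best explains the data under a
single-causal-variant assumption per trait:

    H0  no causal variant for either trait
    H1  a causal variant for trait 1 only
    H2  a causal variant for trait 2 only
    H3  two distinct causal variants, one per trait
    H4  one causal variant shared by both traits

Per-SNP evidence is the Wakefield approximate Bayes factor
log ABF = 0.5 log(V/(V+W)) + (z²/2)(W/(V+W)) with V = se², z = beta/se and
prior effect variance W. Hypothesis likelihoods aggregate configurations
in log space; posteriors weight them by per-configuration priors p1, p2,
p12.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import AssocSummaryStats, MwasSummary

__all__ = [
    "Region",
    "ColocResult",
    "extract_region",
    "log_abf",
    "coloc_abf",
    "classify_evidence",
    "lookup_ms_cpgs",
]

AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class Region:
    """Allele-harmonized, window-restricted intersection of two SNP panels."""

    index_snp: str
    chrom: str
    start: int
    end: int
    gwas: pd.DataFrame
    mqtl: pd.DataFrame
    n_ambiguous_dropped: int = 0
    n_allele_mismatch: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.gwas)


def extract_region(
    gwas: AssocSummaryStats,
    mqtl: AssocSummaryStats,
    index_snp: str,
    window_bp: int = 1_000_000,
) -> Region:
    """SNPs within ±window of the index SNP, shared by both panels.

    mQTL effect alleles are aligned to the GWAS: rows with swapped
    effect/other alleles get their beta sign flipped; rows whose allele
    pair does not match are dropped, as are strand-ambiguous (A/T, C/G)
    SNPs.
    """
    g = gwas.table
    idx_rows = g[g["snp"] == index_snp]
    if idx_rows.empty:
        raise KeyError(f"index SNP {index_snp!r} absent from GWAS")
    chrom = idx_rows["chr"].iloc[0]
    pos = int(idx_rows["pos"].iloc[0])
    start, end = pos - window_bp, pos + window_bp
    gw = g[(g["chr"] == chrom) & (g["pos"].between(start, end))].copy()
    mq = mqtl.table
    mq = mq[mq["snp"].isin(gw["snp"])].copy()
    gw = gw[gw["snp"].isin(mq["snp"])]
    if gw.empty:
        raise ValueError(f"no shared SNPs in window around {index_snp}")

    g_alleles = gw.set_index("snp")[["ea", "oa"]]
    keep_rows = []
    n_amb = 0
    n_mismatch = 0
    for _, row in mq.iterrows():
        ea, oa = str(row["ea"]).upper(), str(row["oa"]).upper()
        if frozenset((ea, oa)) in AMBIGUOUS:
            n_amb += 1
            continue
        g_ea = str(g_alleles.at[row["snp"], "ea"]).upper()
        g_oa = str(g_alleles.at[row["snp"], "oa"]).upper()
        if (ea, oa) == (g_ea, g_oa):
            keep_rows.append(row)
        elif (ea, oa) == (g_oa, g_ea):
            row = row.copy()
            row["beta"] = -row["beta"]
            row["ea"], row["oa"] = g_ea, g_oa
            keep_rows.append(row)
        else:
            n_mismatch += 1
    if not keep_rows:
        raise ValueError(f"no harmonizable SNPs in window around {index_snp}")
    mq2 = pd.DataFrame(keep_rows)
    gw2 = gw[gw["snp"].isin(mq2["snp"])]
    order = gw2["snp"].tolist()
    mq2 = mq2.set_index("snp").loc[order].reset_index()
    gw2 = gw2.reset_index(drop=True)
    return Region(
        index_snp=index_snp,
        chrom=str(chrom),
        start=start,
        end=end,
        gwas=gw2,
        mqtl=mq2,
        n_ambiguous_dropped=n_amb,
        n_allele_mismatch=n_mismatch,
    )


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one SNP.

    log ABF = 0.5 log(V/(V+W)) + (z²/2)(W/(V+W)), V = se², z = beta/se,
    W = prior_sd². Positive values favour a nonzero effect.
    """
    beta = float(beta)
    se = float(se)
    if not np.isfinite(beta) or not np.isfinite(se) or not np.isfinite(prior_sd):
        raise ValueError("non-finite input to log_abf")
    if se <= 0 or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    r = W / (V + W)
    return float(0.5 * np.log(V / (V + W)) + 0.5 * z2 * r)


@dataclass
class ColocResult:
    """Posterior support for H0–H4 in one region, plus per-SNP H4 posteriors."""

    pp: dict[str, float]  # PP0..PP4
    per_snp_h4: pd.Series  # indexed by snp id, sums to 1
    n_snps: int
    priors: tuple[float, float, float]  # p1, p2, p12
    evidence_tier: Literal["strong", "suggestive", "none"] = "none"
    index_snp: str = ""
    cpg: str | None = None

    @property
    def top_snp(self) -> str:
        return str(self.per_snp_h4.idxmax())

    @property
    def top_snp_posterior(self) -> float:
        return float(self.per_snp_h4.max())


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)) for a > b, stable."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    region: Region,
    priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5),
    prior_sd_gwas: float = 0.2,
    prior_sd_mqtl: float = 0.15,
) -> ColocResult:
    """Posterior probabilities of H0–H4 for one region.

    Per-configuration priors are p1 (trait-1-only causal SNP), p2
    (trait-2-only), p12 (shared); configuration likelihoods are products of
    per-SNP ABFs, accumulated by log-sum-exp over the n, n, n(n−1), and n
    single-causal configurations of H1–H4. The returned ``per_snp_h4`` is
    the posterior of each SNP being the shared variant given H4.
    """
    p1, p2, p12 = priors
    if region.n_snps == 0:
        raise ValueError("empty region")
    l1 = np.array(
        [log_abf(b, s, prior_sd_gwas) for b, s in zip(region.gwas["beta"], region.gwas["se"])]
    )
    l2 = np.array(
        [log_abf(b, s, prior_sd_mqtl) for b, s in zip(region.mqtl["beta"], region.mqtl["se"])]
    )
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lH0 = 0.0
    lH1 = np.log(p1) + s1
    lH2 = np.log(p2) + s2
    # sum over ordered distinct pairs = (sum_i)(sum_j) − sum_i (i=j)
    lH3 = np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12)
    lH4 = np.log(p12) + s12
    logs = np.array([lH0, lH1, lH2, lH3, lH4])
    pp = np.exp(logs - logsumexp(logs))
    per_snp = np.exp((l1 + l2) - s12)
    return ColocResult(
        pp={f"PP{i}": float(pp[i]) for i in range(5)},
        per_snp_h4=pd.Series(per_snp, index=region.gwas["snp"].tolist()),
        n_snps=region.n_snps,
        priors=(p1, p2, p12),
        evidence_tier="none",
        index_snp=region.index_snp,
        cpg=(region.mqtl["cpg"].iloc[0] if "cpg" in region.mqtl.columns else None),
    )


def classify_evidence(result: ColocResult) -> Literal["strong", "suggestive", "none"]:
    """Evidence tier: strong if PP4 > 0.8 and PP4/PP3 > 5, else suggestive
    if PP4 > 0.5, else none."""
    pp4 = result.pp["PP4"]
    pp3 = result.pp["PP3"]
    ratio = np.inf if pp3 == 0 else pp4 / pp3
    if pp4 > 0.8 and ratio > 5:
        tier = "strong"
    elif pp4 > 0.5:
        tier = "suggestive"
    else:
        tier = "none"
    result.evidence_tier = tier
    return tier


def lookup_ms_cpgs(
    results: Iterable[ColocResult],
    score_recipes: Iterable[MwasSummary],
    *,
    mw_selections: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """For each region at tier >= suggestive, find score recipes containing
    the colocalized CpG.

    ``mw_selections`` optionally restricts each trait's recipe to its
    methylome-wide-significant CpG set; by default the full recipe is used.
    Returns one row per qualifying region: index SNP, top SNP and its
    posterior, target CpG, and the traits whose recipe contains it.
    """
    recipe_sets: dict[str, set[str]] = {}
    for mwas in score_recipes:
        if mw_selections is not None and mwas.trait_name in mw_selections:
            recipe_sets[mwas.trait_name] = set(mw_selections[mwas.trait_name])
        else:
            recipe_sets[mwas.trait_name] = set(mwas.cpg_ids)
    rows = []
    for res in results:
        if res.evidence_tier not in ("strong", "suggestive"):
            continue
        cpg = res.cpg
        traits = sorted(t for t, s in recipe_sets.items() if cpg is not None and cpg in s)
        rows.append(
            {
                "index_snp": res.index_snp,
                "top_snp": res.top_snp,
                "top_snp_posterior": res.top_snp_posterior,
                "cpg": cpg,
                "traits_containing_cpg": ",".join(traits),
                "tier": res.evidence_tier,
                "PP4": res.pp["PP4"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "index_snp",
            "top_snp",
            "top_snp_posterior",
            "cpg",
            "traits_containing_cpg",
            "tier",
            "PP4",
        ],
    )
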