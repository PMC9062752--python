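"""Typed containers and readers/writers for the pipeline's tabular formats.

All on-disk formats are plain delimited text (tab or comma, auto-detected,
header required): MWAS summary statistics, methylation matrices, phenotype
tables, probe exclusion lists, and GWAS/mQTL association summary statistics.
Validation happens at construction so downstream stages can assume clean
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MwasSummary",
    "MethylationMatrix",
    "PhenotypeTable",
    "CpgExclusionList",
    "AssocSummaryStats",
    "read_mwas_summary",
    "write_mwas_summary",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_exclusion_list",
    "read_assoc_stats",
    "write_assoc_stats",
    "apply_cpg_exclusions",
]

NA_TOKENS = ("", "NA", "NaN", "nan")


def _sniff_sep(path: str | Path) -> str:
    """Detect tab vs comma from the header line. Tab wins if both occur."""
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


# ---------------------------------------------------------------------------
# MWAS summary statistics


@dataclass(frozen=True)
class MwasSummary:
    """Per-CpG effect weights and p-values from a training MWAS.

    The score recipe: each record pairs a CpG probe id with the estimated
    effect per unit methylation and the MWAS p-value used for thresholding.
    Chromosome/position are optional annotation.
    """

    trait_name: str
    table: pd.DataFrame  # columns: cpg, weight, p [, chrom, pos]

    def __post_init__(self) -> None:
        t = self.table
        required = {"cpg", "weight", "p"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"MwasSummary missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ValueError("MwasSummary must be non-empty")
        if t["cpg"].duplicated().any():
            dups = t.loc[t["cpg"].duplicated(), "cpg"].tolist()[:5]
            raise ValueError(f"duplicate CpG ids in MWAS summary: {dups}")
        w = t["weight"].to_numpy(float)
        p = t["p"].to_numpy(float)
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite MWAS weight")
        bad = ~((p > 0) & (p <= 1))
        if bad.any():
            rows = np.flatnonzero(bad)[:5].tolist()
            raise ValueError(f"p-value outside (0,1] at rows {rows}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cpg_ids(self) -> pd.Index:
        return pd.Index(self.table["cpg"])

    def weights(self) -> pd.Series:
        return pd.Series(
            self.table["weight"].to_numpy(float), index=self.table["cpg"], name="weight"
        )

    def p_values(self) -> pd.Series:
        return pd.Series(
            self.table["p"].to_numpy(float), index=self.table["cpg"], name="p"
        )


def read_mwas_summary(
    path: str | Path,
    trait_name: str,
    *,
    cpg_col: str = "cpg",
    weight_col: str = "beta",
    p_col: str = "p",
    duplicates: Literal["error", "first"] = "error",
) -> MwasSummary:
    """Read an MWAS summary-statistic file (TSV/CSV with header).

    Column names are configurable because MWAS exports are heterogeneous;
    duplicate CpG rows are a hard error unless ``duplicates='first'``.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    for col, what in ((cpg_col, "cpg"), (weight_col, "weight"), (p_col, "p")):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} ({what}) in {path}")
    out = pd.DataFrame(
        {
            "cpg": df[cpg_col].astype(str),
            "weight": pd.to_numeric(df[weight_col], errors="raise"),
            "p": pd.to_numeric(df[p_col], errors="raise"),
        }
    )
    for opt_src, opt_dst in (("chr", "chrom"), ("chrom", "chrom"), ("pos", "pos")):
        if opt_src in df.columns and opt_dst not in out.columns:
            out[opt_dst] = df[opt_src]
    if duplicates == "first":
        out = out.drop_duplicates(subset="cpg", keep="first").reset_index(drop=True)
    return MwasSummary(trait_name=trait_name, table=out)


def write_mwas_summary(summary: MwasSummary, path: str | Path) -> None:
    df = summary.table.rename(columns={"weight": "beta", "chrom": "chr"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Methylation matrix


@dataclass
class MethylationMatrix:
    """Samples x CpGs methylation values on the beta or M scale.

    Beta values are methylation fractions, constrained to the open interval
    (0,1); M values are their logit2 transform and only need to be finite.
    """

    values: pd.DataFrame  # index: sample ids, columns: CpG ids
    scale: Literal["beta", "m"]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate CpG ids")
        arr = v.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("methylation matrix contains non-finite values")
        if self.scale == "beta" and (np.any(arr <= 0.0) or np.any(arr >= 1.0)):
            raise ValueError("beta values must lie strictly in (0, 1)")
        if self.scale not in ("beta", "m"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_cpgs(self, cpgs: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.values[list(cpgs)], self.scale)


def read_methylation_matrix(
    path: str | Path,
    scale: Literal["beta", "m"],
    *,
    cpgs_in_rows: bool = False,
) -> MethylationMatrix:
    """Read a delimited methylation matrix.

    Default orientation has samples in rows (first column = sample id);
    ``cpgs_in_rows=True`` reads the transpose (first column = CpG id).
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if cpgs_in_rows:
        df = df.T
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    return MethylationMatrix(df.astype(float), scale)


def write_methylation_matrix(
    matrix: MethylationMatrix, path: str | Path, *, cpgs_in_rows: bool = False
) -> None:
    df = matrix.values.T if cpgs_in_rows else matrix.values
    df.to_csv(path, sep="\t", index_label="cpg" if cpgs_in_rows else "sample_id")


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass
class PhenotypeTable:
    """Per-sample outcomes and covariates.

    Missing values are permitted (and tracked), never imputed here:
    complete-case handling is a per-model decision downstream. Cell
    proportion columns, when declared, must lie in [0, 1].
    """

    table: pd.DataFrame  # index: sample ids
    cell_columns: tuple[str, ...] = ()
    pc_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        for col in self.cell_columns:
            if col not in self.table.columns:
                raise ValueError(f"declared cell column {col!r} absent")
            vals = self.table[col].dropna().to_numpy(float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"cell proportion column {col!r} outside [0,1]")
        for col in self.pc_columns:
            if col not in self.table.columns:
                raise ValueError(f"declared PC column {col!r} absent")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def missingness(self) -> pd.Series:
        """Count of missing entries per column."""
        return self.table.isna().sum()

    def __len__(self) -> int:
        return len(self.table)


def read_phenotypes(
    path: str | Path,
    *,
    sample_col: str = "sample_id",
    cell_columns: Iterable[str] = (),
    pc_columns: Iterable[str] = (),
) -> PhenotypeTable:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=list(NA_TOKENS), keep_default_na=False)
    if sample_col not in df.columns:
        raise ValueError(f"missing sample id column {sample_col!r}")
    df = df.set_index(sample_col)
    df.index = df.index.astype(str)
    return PhenotypeTable(df, tuple(cell_columns), tuple(pc_columns))


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Probe exclusion lists


@dataclass(frozen=True)
class CpgExclusionList:
    """A set of probes to drop before scoring (cross-reactive, polymorphic, QC)."""

    cpg_ids: frozenset[str]
    reason: Literal["cross_reactive", "polymorphic", "qc_fail"]

    def __post_init__(self) -> None:
        if not self.cpg_ids:
            raise ValueError("exclusion list is empty")
        for cid in self.cpg_ids:
            if not cid or any(c.isspace() for c in cid):
                raise ValueError(f"invalid probe label {cid!r}")

    def __len__(self) -> int:
        return len(self.cpg_ids)


def read_exclusion_list(
    path: str | Path,
    reason: Literal["cross_reactive", "polymorphic", "qc_fail"],
) -> CpgExclusionList:
    """One CpG id per line, plain text, no header."""
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return CpgExclusionList(frozenset(ids), reason)


def apply_cpg_exclusions(
    matrix: MethylationMatrix, *lists: CpgExclusionList
) -> tuple[MethylationMatrix, dict[str, int]]:
    """Drop excluded probes, preserving survivor column order.

    Returns the filtered matrix and the count of probes removed per reason
    (a probe excluded by several lists counts toward each reason; the matrix
    drops the union). Removing every probe is an error.
    """
    present = set(matrix.cpg_ids)
    union: set[str] = set()
    removed_by_reason: dict[str, int] = {}
    for lst in lists:
        hit = lst.cpg_ids & present
        removed_by_reason[lst.reason] = removed_by_reason.get(lst.reason, 0) + len(hit)
        union |= hit
    keep = [c for c in matrix.cpg_ids if c not in union]
    if not keep:
        raise ValueError("all CpGs excluded: empty matrix")
    return MethylationMatrix(matrix.values[keep], matrix.scale), removed_by_reason


# ---------------------------------------------------------------------------
# GWAS / mQTL association summary statistics


@dataclass
class AssocSummaryStats:
    """SNP association summary statistics (GWAS, or mQTL with target CpGs).

    Coordinates are 1-based. mQTL rows must carry a target CpG id in the
    ``cpg`` column; GWAS tables omit it.
    """

    table: pd.DataFrame  # snp, chr, pos, ea, oa, beta, se, n [, maf][, cpg]
    kind: Literal["gwas", "mqtl"] = "gwas"

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp", "chr", "pos", "ea", "oa", "beta", "se", "n"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"AssocSummaryStats missing columns: {sorted(missing)}")
        se = t["se"].to_numpy(float)
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            raise ValueError("standard errors must be finite and > 0")
        if not np.all(np.isfinite(t["beta"].to_numpy(float))):
            raise ValueError("non-finite beta")
        if "maf" in t.columns:
            maf = t["maf"].dropna().to_numpy(float)
            if np.any(maf <= 0) or np.any(maf > 0.5):
                raise ValueError("maf must lie in (0, 0.5]")
        if self.kind == "mqtl":
            if "cpg" not in t.columns or t["cpg"].isna().any():
                raise ValueError("mQTL rows must carry a target CpG id")
        # per-id (chr,pos,allele-set) consistency
        key = t.groupby("snp").agg(
            chr_n=("chr", "nunique"), pos_n=("pos", "nunique")
        )
        bad = key[(key["chr_n"] > 1) | (key["pos_n"] > 1)]
        if len(bad):
            raise ValueError(f"inconsistent coordinates for snp ids: {bad.index[:5].tolist()}")

    def __len__(self) -> int:
        return len(self.table)


def read_assoc_stats(
    path: str | Path, kind: Literal["gwas", "mqtl"] = "gwas"
) -> AssocSummaryStats:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    return AssocSummaryStats(df, kind)


def write_assoc_stats(stats: AssocSummaryStats, path: str | Path) -> None:
    stats.table.to_csv(path, sep="\t", index=False)
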