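"""Demographic comparison tables: chi-square and Welch t tests.

Case/control demographic tables compare groups with a Pearson chi-square
(no continuity correction) for categorical variables and a Welch
unequal-variance t-test for continuous ones, exactly as published cohort
demographics tables do. Both tests are computable from summary data alone
(cell counts; group means/SDs/Ns), so published tables can be re-derived
without individual-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeTable

__all__ = [
    "ContingencyTable",
    "SummaryStatsPair",
    "pearson_chisq",
    "welch_t",
    "demographics_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Groups x categories count table."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")


@dataclass(frozen=True)
class SummaryStatsPair:
    """Mean, SD, and N for one variable in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


def pearson_chisq(
    table: ContingencyTable, drop_zero_categories: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square statistic, df, and upper-tail p.

    The classic sum of (O−E)²/E with no continuity correction; df =
    (rows−1)(cols−1) after optional removal of all-zero categories.
    """
    counts = np.asarray(table.counts, float)
    col_tot = counts.sum(axis=0)
    if drop_zero_categories:
        counts = counts[:, col_tot > 0]
    elif np.any(col_tot == 0):
        raise ValueError("zero-total category; pass drop_zero_categories=True")
    row_tot = counts.sum(axis=1)
    if np.any(row_tot == 0):
        raise ValueError("zero-total group row")
    grand = counts.sum()
    if grand == 0:
        raise ValueError("empty table")
    expected = np.outer(row_tot, counts.sum(axis=0)) / grand
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if df < 1:
        raise ValueError("table needs at least 2 rows and 2 non-empty columns")
    return stat, df, float(stats.chi2.sf(stat, df))


def welch_t(a: SummaryStatsPair, b: SummaryStatsPair) -> tuple[float, float, float]:
    """Welch unequal-variance t (group b minus group a), df, two-sided p.

    t = (mean_b − mean_a) / sqrt(sd_a²/n_a + sd_b²/n_b) with the
    Welch–Satterthwaite degrees of freedom.
    """
    va = a.sd**2 / a.n
    vb = b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("zero variance in both groups")
    t = (b.mean - a.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def demographics_table(
    pheno: PhenotypeTable,
    group: str,
    *,
    continuous: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
    missing_as_category: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-variable group comparison with the appropriate test per type.

    Continuous variables get a Welch t-test on complete cases; categorical
    variables a Pearson chi-square, with missing values counted as a
    category only where ``missing_as_category`` says so (never inferred).
    """
    data = pheno.table
    groups = sorted(data[group].dropna().unique())
    if len(groups) != 2:
        raise ValueError("group column must be binary")
    g0 = data[data[group] == groups[0]]
    g1 = data[data[group] == groups[1]]
    mac = missing_as_category or {}
    rows = []
    for var in continuous:
        a = g1[var].dropna()
        b = g0[var].dropna()
        t, df, p = welch_t(
            SummaryStatsPair(float(a.mean()), float(a.std(ddof=1)), len(a)),
            SummaryStatsPair(float(b.mean()), float(b.std(ddof=1)), len(b)),
        )
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "test": "welch_t",
                "statistic": t,
                "df": df,
                "p": p,
                "group_a_summary": f"{a.mean():.4g} ({a.std(ddof=1):.4g})",
                "group_b_summary": f"{b.mean():.4g} ({b.std(ddof=1):.4g})",
            }
        )
    for var in categorical:
        s1 = g1[var]
        s0 = g0[var]
        if mac.get(var, False):
            s1 = s1.astype(object).where(s1.notna(), "Missing")
            s0 = s0.astype(object).where(s0.notna(), "Missing")
        else:
            s1, s0 = s1.dropna(), s0.dropna()
        cats = sorted(set(s1.unique()) | set(s0.unique()), key=str)
        counts = np.array(
            [
                [int((s1 == c).sum()) for c in cats],
                [int((s0 == c).sum()) for c in cats],
            ]
        )
        stat, df, p = pearson_chisq(
            ContingencyTable(counts, ("cases", "controls"), tuple(map(str, cats))),
            drop_zero_categories=True,
        )
        rows.append(
            {
                "variable": var,
                "type": "categorical",
                "test": "pearson_chisq",
                "statistic": stat,
                "df": float(df),
                "p": p,
                "group_a_summary": "/".join(str(c) for c in counts[0]),
                "group_b_summary": "/".join(str(c) for c in counts[1]),
            }
        )
    return pd.DataFrame(rows)
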