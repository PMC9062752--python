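"""Methylation scores: weighted sums of trait-associated CpGs.

A methylation score (MS) for a trait is the per-sample sum of methylation
values at CpGs passing an MWAS p-value threshold, each multiplied by its
MWAS effect weight — the methylation analogue of a polygenic score. The
methylome-wide (MW) threshold is the Bonferroni cutoff alpha / n_tests;
looser thresholds (0.01, 0.05, 0.1, 0.5) admit nested supersets of CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import MethylationMatrix, MwasSummary

__all__ = [
    "ThresholdSpec",
    "DEFAULT_THRESHOLDS",
    "OverlapReport",
    "select_cpgs",
    "compute_ms",
    "standardize_scores",
    "MethylationScorer",
    "ScoreSet",
    "build_score_set",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """A p-value inclusion threshold for score construction.

    ``p_cutoff`` is either a number in (0,1] or the string ``"MW"``, in
    which case the cutoff is the Bonferroni family-wise level
    ``mw_alpha / mw_tests`` (``mw_tests`` defaults to the number of CpGs in
    the MWAS file when resolved). CpGs with p exactly equal to the cutoff
    are included.
    """

    label: str
    p_cutoff: float | str = "MW"
    mw_alpha: float = 0.05
    mw_tests: int | None = None

    def resolve(self, n_tests_default: int) -> float:
        if isinstance(self.p_cutoff, str):
            if self.p_cutoff != "MW":
                raise ValueError(f"unknown cutoff {self.p_cutoff!r}")
            n = self.mw_tests if self.mw_tests is not None else n_tests_default
            if n <= 0:
                raise ValueError("mw_tests must be positive")
            return self.mw_alpha / n
        cut = float(self.p_cutoff)
        if not (0 < cut <= 1):
            raise ValueError(f"cutoff {cut} outside (0, 1]")
        return cut


DEFAULT_THRESHOLDS: tuple[ThresholdSpec, ...] = (
    ThresholdSpec("MW", "MW"),
    ThresholdSpec("0.01", 0.01),
    ThresholdSpec("0.05", 0.05),
    ThresholdSpec("0.1", 0.1),
    ThresholdSpec("0.5", 0.5),
)


@dataclass(frozen=True)
class OverlapReport:
    """Accounting of recipe CpGs vs CpGs available on the target array."""

    n_in_recipe: int
    n_available: int
    n_used: int

    @property
    def overlap_fraction(self) -> float:
        return self.n_used / self.n_in_recipe if self.n_in_recipe else float("nan")


def select_cpgs(
    mwas: MwasSummary, spec: ThresholdSpec, available: Iterable[str]
) -> tuple[list[str], OverlapReport]:
    """CpGs passing the threshold, intersected with the target array.

    Returns the selected ids (MWAS file order) and an overlap report. An
    empty selection is an error: the threshold is too strict for this
    recipe/array combination.
    """
    avail = set(available)
    if not avail:
        raise ValueError("available CpG set is empty")
    cutoff = spec.resolve(len(mwas))
    p = mwas.p_values()
    passing = p.index[p.to_numpy() <= cutoff]
    selected = [c for c in passing if c in avail]
    report = OverlapReport(
        n_in_recipe=len(passing), n_available=len(avail), n_used=len(selected)
    )
    if not selected:
        raise ValueError(
            f"no CpGs selected at threshold {spec.label} "
            f"(cutoff {cutoff:.3g}); try a looser threshold"
        )
    return selected, report


def compute_ms(matrix: MethylationMatrix, weights: Mapping[str, float]) -> pd.Series:
    """score_i = sum_j w_j * m_ij — the raw weighted sum, no normalization.

    Every weighted CpG must be present in the matrix (``select_cpgs`` is
    responsible for the intersection).
    """
    cpgs = list(weights)
    missing = [c for c in cpgs if c not in matrix.values.columns]
    if missing:
        raise KeyError(f"weights for CpGs absent from matrix: {missing[:5]}")
    w = np.array([weights[c] for c in cpgs], float)
    scores = matrix.values[cpgs].to_numpy(float) @ w
    return pd.Series(scores, index=matrix.sample_ids, name="score")


def standardize_scores(scores: pd.Series) -> pd.Series:
    """Z-score (mean 0, sample-sd 1). Fails on < 2 samples or zero variance."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = float(scores.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance: cannot standardize")
    return (scores - scores.mean()) / sd


class MethylationScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: MWAS recipe -> per-sample scores.

    ``fit`` resolves thresholds and CpG overlap against the target matrix;
    ``transform`` computes one score column per threshold.

    Parameters
    ----------
    mwas : MwasSummary
        The training-MWAS recipe (weights + p-values).
    thresholds : sequence of ThresholdSpec
        Defaults to MW, 0.01, 0.05, 0.1, 0.5.
    standardize : bool
        Z-score each threshold's column after computation.
    """

    def __init__(
        self,
        mwas: MwasSummary | None = None,
        thresholds: Sequence[ThresholdSpec] = DEFAULT_THRESHOLDS,
        standardize: bool = False,
    ):
        self.mwas = mwas
        self.thresholds = thresholds
        self.standardize = standardize

    def fit(self, matrix: MethylationMatrix, y=None):
        if self.mwas is None:
            raise ValueError("an MwasSummary recipe is required")
        weights = self.mwas.weights()
        self.selection_: dict[str, list[str]] = {}
        self.reports_: dict[str, OverlapReport] = {}
        self.weights_: dict[str, pd.Series] = {}
        for spec in self.thresholds:
            sel, rep = select_cpgs(self.mwas, spec, matrix.cpg_ids)
            self.selection_[spec.label] = sel
            self.reports_[spec.label] = rep
            self.weights_[spec.label] = weights.loc[sel]
        return self

    def transform(self, matrix: MethylationMatrix) -> pd.DataFrame:
        check_is_fitted(self, "selection_")
        out = {}
        for label, w in self.weights_.items():
            s = compute_ms(matrix, w.to_dict())
            out[label] = standardize_scores(s) if self.standardize else s
        return pd.DataFrame(out, index=matrix.sample_ids)


@dataclass
class ScoreSet:
    """Per-sample methylation scores per (trait, threshold).

    ``scores`` maps (trait, threshold label) to a sample-indexed Series;
    ``reports`` carries the recipe/array overlap accounting.
    """

    scores: dict[tuple[str, str], pd.Series] = field(default_factory=dict)
    reports: dict[tuple[str, str], OverlapReport] = field(default_factory=dict)
    standardized: bool = False

    def add(
        self, trait: str, threshold: str, scores: pd.Series, report: OverlapReport
    ) -> None:
        if not np.all(np.isfinite(scores.to_numpy(float))):
            raise ValueError("scores must be finite")
        if report.n_used > report.n_in_recipe:
            raise ValueError("n_cpgs_used cannot exceed recipe size")
        self.scores[(trait, threshold)] = scores
        self.reports[(trait, threshold)] = report

    def get(self, trait: str, threshold: str) -> pd.Series:
        return self.scores[(trait, threshold)]

    def traits(self) -> list[str]:
        seen: list[str] = []
        for trait, _ in self.scores:
            if trait not in seen:
                seen.append(trait)
        return seen

    def thresholds_for(self, trait: str) -> list[str]:
        return [th for tr, th in self.scores if tr == trait]

    def to_frame(self) -> pd.DataFrame:
        """Long format: sample_id, trait, threshold, score, n_cpgs_used."""
        rows = []
        for (trait, th), s in self.scores.items():
            rep = self.reports[(trait, th)]
            df = s.rename("score").to_frame()
            df["trait"] = trait
            df["threshold"] = th
            df["n_cpgs_used"] = rep.n_used
            rows.append(df.reset_index(names="sample_id"))
        return pd.concat(rows, ignore_index=True)[
            ["sample_id", "trait", "threshold", "score", "n_cpgs_used"]
        ]


def build_score_set(
    matrix: MethylationMatrix,
    recipes: Iterable[MwasSummary],
    thresholds: Sequence[ThresholdSpec] = DEFAULT_THRESHOLDS,
    *,
    standardize: bool = False,
    skip_empty: bool = True,
) -> ScoreSet:
    """Score every trait recipe at every threshold against one matrix.

    Thresholds with an empty selection are skipped (with ``skip_empty``) —
    recipes restricted to genome-wide-significant CpGs cannot support the
    looser thresholds.
    """
    out = ScoreSet(standardized=standardize)
    for mwas in recipes:
        weights = mwas.weights()
        for spec in thresholds:
            try:
                sel, rep = select_cpgs(mwas, spec, matrix.cpg_ids)
            except ValueError:
                if skip_empty:
                    continue
                raise
            s = compute_ms(matrix, weights.loc[sel].to_dict())
            if standardize:
                s = standardize_scores(s)
            out.add(mwas.trait_name, spec.label, s, rep)
    return out
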