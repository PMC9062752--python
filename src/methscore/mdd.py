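"""L1-penalized MDD methylation score and ROC/DeLong evaluation.

The MDD score is trained in two stages: depression status (0/1) is first
regressed on covariates (age, sex, genetic PCs) by ordinary least squares
and the residuals become the continuous dependent variable for a LASSO
(elastic-net mixing parameter 1) over all CpGs, with the penalty chosen by
10-fold cross-validation. Scores from competing classifiers on the same
test samples are compared by AUC and the DeLong test for correlated ROC
curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .io import MethylationMatrix, PhenotypeTable

__all__ = [
    "split_cohort",
    "PenalizedMddScorer",
    "train_penalized_score",
    "roc_auc",
    "RocComparison",
    "delong_test",
]


def split_cohort(
    pheno: PhenotypeTable,
    by: str | None = None,
    *,
    fraction: float | None = None,
    seed: int | None = None,
) -> tuple[pd.Index, pd.Index]:
    """Partition samples into train/test, by a two-level column or a fraction.

    With ``by``, the column must have exactly two levels; the first (sorted)
    level becomes the training set. With ``fraction``, a seeded random
    split is drawn instead.
    """
    ids = pheno.sample_ids
    if by is not None:
        col = pheno.table[by]
        levels = sorted(col.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"split column {by!r} has {len(levels)} levels, need 2")
        train = ids[col == levels[0]]
        test = ids[col == levels[1]]
        if len(train) == 0 or len(test) == 0:
            raise ValueError("a split level has zero samples")
        return train, test
    if fraction is None:
        raise ValueError("give either a split column or a fraction")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    if n_train in (0, len(ids)):
        raise ValueError("fraction leaves an empty split")
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]


class PenalizedMddScorer(BaseEstimator, RegressorMixin):
    """Two-stage LASSO methylation predictor of depression status.

    Stage 1 residualizes the 0/1 outcome on covariates with a linear
    probability model; stage 2 fits an L1-penalized linear regression of
    those residuals on every CpG, with lambda chosen by cross-validation
    (minimum mean CV error by default, the 1-SE rule behind a flag). Folds
    are stratified by case status and seeded.

    Fitted attributes: ``selected_cpgs_`` (nonzero-weight probes),
    ``weights_``, ``lambda_chosen_``, ``intercept_``, ``stage1_``.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        folds: int = 10,
        seed: int = 0,
        rule: str = "min",  # or "1se"
        n_alphas: int = 50,
    ):
        self.covariates = covariates
        self.folds = folds
        self.seed = seed
        self.rule = rule
        self.n_alphas = n_alphas

    def fit(self, matrix: MethylationMatrix, pheno: PhenotypeTable):
        covs = list(self.covariates or [])
        ph = pheno.table.loc[matrix.sample_ids]
        use = ph[[c for c in covs]].notna().all(axis=1) if covs else pd.Series(True, index=ph.index)
        ph = ph[use]
        if "mdd" not in ph.columns:
            raise KeyError("phenotype table needs an 'mdd' column")
        mdd = ph["mdd"].to_numpy(float)
        if set(np.unique(mdd)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if mdd.min() == mdd.max():
            raise ValueError("all-constant outcome")
        if len(mdd) < 2 * self.folds:
            raise ValueError(f"need at least {2 * self.folds} samples for {self.folds}-fold CV")
        X = matrix.values.loc[ph.index].to_numpy(float)

        # stage 1: linear-probability residuals of MDD on covariates
        if covs:
            C = pd.get_dummies(ph[covs], drop_first=True, dtype=float).to_numpy(float)
            stage1 = LinearRegression().fit(C, mdd)
            resid = mdd - stage1.predict(C)
            self.stage1_ = stage1
        else:
            resid = mdd - mdd.mean()
            self.stage1_ = None

        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        cv_splits = list(skf.split(X, mdd.astype(int)))
        lcv = LassoCV(cv=cv_splits, alphas=self.n_alphas, random_state=self.seed)
        lcv.fit(X, resid)
        if self.rule == "1se":
            mean_mse = lcv.mse_path_.mean(axis=1)
            se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
            i_min = int(np.argmin(mean_mse))
            limit = mean_mse[i_min] + se[i_min]
            # alphas_ are decreasing: pick the largest alpha within 1 SE
            ok = np.flatnonzero(mean_mse <= limit)
            alpha = float(lcv.alphas_[ok[0]])
            coefs, intercept = _lasso_at(X, resid, alpha)
        elif self.rule == "min":
            alpha = float(lcv.alpha_)
            coefs, intercept = lcv.coef_, float(lcv.intercept_)
        else:
            raise ValueError(f"unknown lambda rule {self.rule!r}")

        nz = np.flatnonzero(coefs)
        self.lambda_chosen_ = alpha
        self.cv_alphas_ = lcv.alphas_
        self.cv_mse_path_ = lcv.mse_path_
        self.intercept_ = float(intercept)
        self.selected_cpgs_ = list(matrix.cpg_ids[nz])
        self.weights_ = pd.Series(coefs[nz], index=matrix.cpg_ids[nz], name="weight")
        self.covariates_ = tuple(covs)
        self.n_train_ = len(mdd)
        return self

    def predict(self, matrix: MethylationMatrix) -> pd.Series:
        """Per-sample MDD methylation score: weighted sum over selected CpGs."""
        check_is_fitted(self, "weights_")
        if len(self.weights_) == 0:
            return pd.Series(
                np.full(len(matrix.sample_ids), self.intercept_),
                index=matrix.sample_ids,
                name="mdd_score",
            )
        missing = [c for c in self.weights_.index if c not in matrix.values.columns]
        if missing:
            raise KeyError(f"selected CpGs absent from matrix: {missing[:5]}")
        X = matrix.values[list(self.weights_.index)].to_numpy(float)
        return pd.Series(
            self.intercept_ + X @ self.weights_.to_numpy(),
            index=matrix.sample_ids,
            name="mdd_score",
        )


def _lasso_at(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Coefficients of a plain Lasso at one alpha (for the 1-SE rule)."""
    from sklearn.linear_model import Lasso

    model = Lasso(alpha=alpha).fit(X, y)
    return model.coef_, float(model.intercept_)


def train_penalized_score(
    matrix: MethylationMatrix,
    pheno: PhenotypeTable,
    covariates: list[str],
    folds: int = 10,
    seed: int = 0,
) -> PenalizedMddScorer:
    """Fit the two-stage LASSO MDD score on a training cohort."""
    return PenalizedMddScorer(covariates=covariates, folds=folds, seed=seed).fit(
        matrix, pheno
    )


def roc_auc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> float:
    """AUC as the Mann–Whitney probability, ties counted one half.

    Equals P(score_case > score_control) + 0.5 P(equal) over all
    case/control pairs, computed via midranks.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class RocComparison:
    """Paired AUC comparison between two scores on identical samples."""

    auc_a: float
    auc_b: float
    delong_d: float
    p_value: float
    n_cases: int
    n_controls: int


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (placement values) per case and control."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # midrank formulation (handles ties as 1/2)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n  # per-case placement
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # per-control placement
    return v10, v01


def delong_test(
    scores_a: np.ndarray | pd.Series,
    scores_b: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
) -> RocComparison:
    """DeLong test for the difference between two correlated AUCs.

    Uses the structural-components covariance estimate; D is the
    standardized AUC difference and the p-value is two-sided normal. Scores
    must be paired on the same samples.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    y = np.asarray(labels, float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores and labels must be paired (same length)")
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("labels must be 0/1")
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    v10a, v01a = _placements(a, y)
    v10b, v01b = _placements(b, y)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    diff = auc_a - auc_b
    if m < 2 or n < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        if diff == 0.0:
            return RocComparison(auc_a, auc_b, 0.0, 1.0, m, n)
        raise ValueError("degenerate placement variance with nonzero AUC difference")
    d = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(d)))
    return RocComparison(auc_a, auc_b, float(d), max(min(p, 1.0), np.nextafter(0, 1)), m, n)
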