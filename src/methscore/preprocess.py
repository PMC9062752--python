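"""Scale transforms, covariate residualization, and methylation PCs.

The residualization here is the fixed-effects analogue of the cohorts'
pre-correction pipelines: each CpG column is replaced by its least-squares
residual on an intercept plus the chosen covariates, after which methylation
principal components can be computed on the residualized, column-centered
matrix. Pedigree/mixed-model corrections are out of scope by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import MethylationMatrix, PhenotypeTable

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "CovariateResidualizer",
    "ResidualizedMatrix",
    "residualize",
    "MethylationPCA",
    "methylation_pcs",
]


def beta_to_m(matrix: MethylationMatrix) -> MethylationMatrix:
    """M = log2(beta / (1 - beta)), elementwise. Input must be beta-scale."""
    if matrix.scale != "beta":
        raise ValueError("matrix is already on the M scale")
    b = matrix.values.to_numpy(float)
    m = np.log2(b / (1.0 - b))
    return MethylationMatrix(
        pd.DataFrame(m, index=matrix.sample_ids, columns=matrix.cpg_ids), "m"
    )


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """beta = 2^M / (2^M + 1): the inverse of :func:`beta_to_m`."""
    if matrix.scale != "m":
        raise ValueError("matrix is already on the beta scale")
    m = matrix.values.to_numpy(float)
    b = 1.0 / (1.0 + np.exp2(-m))  # = 2^M/(2^M+1), stable for large |M|
    return MethylationMatrix(
        pd.DataFrame(b, index=matrix.sample_ids, columns=matrix.cpg_ids), "beta"
    )


@dataclass
class ResidualizedMatrix:
    """A methylation matrix orthogonalized against a covariate design."""

    matrix: MethylationMatrix
    covariates_used: tuple[str, ...]
    n_excluded_incomplete: int = 0

    @property
    def values(self) -> pd.DataFrame:
        return self.matrix.values


def _design_matrix(pheno: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + covariates; categoricals expand to dummy columns."""
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for c in covariates:
        s = pheno[c]
        if s.dtype.kind in "OUb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(float))
                names.append(dc)
        else:
            cols.append(s.to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design (rank {rank} < {X.shape[1]}); "
            f"check collinearity among {names[1:]}"
        )
    return X


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Per-CpG least-squares residualization on phenotype covariates.

    Parameters
    ----------
    covariates : list of str
        Phenotype columns to regress out (an intercept is always included).
        Samples with any missing covariate are dropped (complete-case).
    """

    def __init__(self, covariates: list[str] | None = None):
        self.covariates = covariates

    def fit(self, matrix: MethylationMatrix, pheno: PhenotypeTable):
        covs = list(self.covariates or [])
        ph = pheno.table.loc[matrix.sample_ids]
        complete = ph[covs].notna().all(axis=1) if covs else pd.Series(True, index=ph.index)
        self.complete_ids_ = ph.index[complete]
        self.n_excluded_ = int((~complete).sum())
        self.design_ = _design_matrix(ph.loc[self.complete_ids_], covs)
        # hat-complement projector applied lazily in transform via lstsq
        self.covariates_ = tuple(covs)
        return self

    def transform(self, matrix: MethylationMatrix) -> ResidualizedMatrix:
        check_is_fitted(self, "design_")
        Y = matrix.values.loc[self.complete_ids_].to_numpy(float)
        coef, *_ = np.linalg.lstsq(self.design_, Y, rcond=None)
        resid = Y - self.design_ @ coef
        out = MethylationMatrix(
            pd.DataFrame(resid, index=self.complete_ids_, columns=matrix.cpg_ids),
            matrix.scale,
        )
        return ResidualizedMatrix(out, self.covariates_, self.n_excluded_)

    def fit_transform(self, matrix, pheno=None, **kw):  # noqa: D102
        return self.fit(matrix, pheno).transform(matrix)


def residualize(
    matrix: MethylationMatrix, pheno: PhenotypeTable, covariates: list[str]
) -> ResidualizedMatrix:
    """Regress each CpG on intercept + covariates; return residuals."""
    return CovariateResidualizer(covariates).fit_transform(matrix, pheno)


class MethylationPCA(BaseEstimator, TransformerMixin):
    """Principal components of a (residualized) methylation matrix.

    Scores are the first k right-singular-direction projections of the
    column-centered matrix. Signs are fixed deterministically: each
    component is flipped so its largest-magnitude sample score is positive.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, matrix: MethylationMatrix | ResidualizedMatrix, y=None):
        vals = matrix.values
        X = vals.to_numpy(float)
        k = self.n_components
        if k > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                f"n_components={k} exceeds min(n_samples-1, n_cpgs)="
                f"{min(X.shape[0] - 1, X.shape[1])}"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if k > int(np.sum(s > s[0] * 1e-12)):
            raise ValueError(f"n_components={k} exceeds matrix rank")
        scores = U[:, :k] * s[:k]
        flip = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        self.components_ = Vt[:k] * flip[:, None]
        self.singular_values_ = s[:k]
        total_var = float(np.sum(s**2))
        self.explained_variance_ratio_ = s[:k] ** 2 / total_var if total_var else s[:k] * 0
        self.sample_index_ = vals.index
        self.scores_ = pd.DataFrame(
            scores * flip,
            index=vals.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return self

    def transform(self, matrix: MethylationMatrix | ResidualizedMatrix) -> pd.DataFrame:
        check_is_fitted(self, "components_")
        X = matrix.values.to_numpy(float) - self.mean_
        return pd.DataFrame(
            X @ self.components_.T,
            index=matrix.values.index,
            columns=[f"PC{i + 1}" for i in range(self.components_.shape[0])],
        )


def methylation_pcs(
    matrix: MethylationMatrix | ResidualizedMatrix, k: int
) -> pd.DataFrame:
    """Per-sample scores on the first k methylation PCs."""
    return MethylationPCA(n_components=k).fit(matrix).scores_
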