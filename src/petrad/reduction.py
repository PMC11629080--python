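"""Feature filtering and per-category principal components.

Two scikit-learn-style transformers implement the reduction stage:

* :class:`CoVFilter` removes near-constant features — columns whose
  coefficient of variation, 100*SD/|mean|, is at or below a threshold
  (default 3%).  Columns with mean 0 and SD 0 are removed; mean 0 with
  SD > 0 (undefined CoV) counts as high-variation and is retained.
* :class:`CategoryPCA` z-scores the surviving columns of one feature
  category and eigen-decomposes their correlation matrix; scores are the
  standardized data projected on the eigenvectors, with each component's
  sign fixed so its largest-magnitude loading is positive.  Standardization
  parameters are stored so held-out patients can be projected without
  refitting (needed for honest cross-validation).

Both compose with sklearn pipelines (get_params/set_params, fitted
attributes with trailing underscores).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["CoVFilter", "CategoryPCA", "cov_filter", "category_pca", "spearman_vs_mtv",
           "impute_cohort_median"]


def impute_cohort_median(table: pd.DataFrame) -> pd.DataFrame:
    """Replace non-finite feature values by the column's cohort median."""
    out = table.copy()
    num = out.select_dtypes(include=[np.number]).columns
    for c in num:
        col = out[c].to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            col[bad] = med if np.isfinite(med) else 0.0
            out[c] = col
    return out


class CoVFilter(BaseEstimator, TransformerMixin):
    """Drop columns with coefficient of variation <= ``threshold_pct`` %."""

    def __init__(self, threshold_pct: float = 3.0):
        self.threshold_pct = threshold_pct

    def fit(self, X, y=None):
        X = self._as_frame(X)
        if len(X) < 2:
            raise ValueError("CoVFilter requires at least 2 patients")
        mean = X.mean(axis=0).to_numpy()
        sd = X.std(axis=0, ddof=1).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = 100.0 * sd / np.abs(mean)
        keep = np.where(np.abs(mean) < 1e-300, sd > 0, cov > self.threshold_pct)
        if not keep.any():
            raise ValueError(
                f"CoV filter at {self.threshold_pct}% removed every column "
                f"(max CoV {np.nanmax(cov):.3g}%)"
            )
        self.feature_names_in_ = np.asarray(X.columns)
        self.support_ = keep
        self.cov_pct_ = cov
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = self._as_frame(X)
        return X.loc[:, self.feature_names_in_[self.support_]]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return self.feature_names_in_[self.support_]

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))


class CategoryPCA(BaseEstimator, TransformerMixin):
    """PCA of z-scored features (correlation-matrix eigendecomposition).

    Components are computed to ``min(rank, max_components)``; downstream
    models consume scores 1..3.  Fitted attributes: ``mean_``, ``scale_``,
    ``components_`` (rows = components, orthonormal), ``explained_variance_``
    and ``explained_variance_ratio_`` (nonincreasing).
    """

    def __init__(self, max_components: int = 10):
        self.max_components = max_components

    def fit(self, X, y=None):
        X = np.asarray(self._values(X), dtype=float)
        n, p = X.shape
        if n <= 1:
            raise ValueError("CategoryPCA requires more than one patient")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 1e-12, sd, 1.0)
        Z = (X - self.mean_) / self.scale_
        C = np.cov(Z.T, ddof=1) if p > 1 else np.atleast_2d(np.cov(Z.T, ddof=1))
        C = np.atleast_2d(C)
        w, V = linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = np.maximum(w[order], 0.0), V[:, order]
        rank = int(np.sum(w > max(w[0], 1e-30) * 1e-10))
        k = min(self.max_components, p, max(rank, 1))
        V = V[:, :k]
        # sign convention: largest-|loading| entry of each component positive
        for j in range(k):
            i = np.argmax(np.abs(V[:, j]))
            if V[i, j] < 0:
                V[:, j] = -V[:, j]
        self.components_ = V.T
        self.explained_variance_ = w[:k]
        self.explained_variance_ratio_ = w[:k] / w.sum() if w.sum() > 0 else w[:k]
        self.rank_ = rank
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(self._values(X), dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_.T

    @staticmethod
    def _values(X):
        return X.to_numpy() if isinstance(X, pd.DataFrame) else X


def cov_filter(table: pd.DataFrame, threshold_pct: float = 3.0) -> pd.DataFrame:
    """Functional wrapper over :class:`CoVFilter`."""
    return CoVFilter(threshold_pct).fit_transform(table)


def category_pca(table: pd.DataFrame, max_components: int = 10) -> tuple[np.ndarray, CategoryPCA]:
    """Fit PCA on one category's columns; returns (scores, fitted transformer)."""
    est = CategoryPCA(max_components=max_components).fit(table)
    return est.transform(table), est


def spearman_vs_mtv(scores: np.ndarray, mtv: np.ndarray):
    """Spearman rank correlation of each PC score column against MTV.

    Returns a DataFrame with per-component rho and large-sample p (average
    ranks for ties).  Constant inputs yield NaN with a flag column.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and len(np.asarray(mtv)) != 1:
        scores = scores.T
    mtv = np.asarray(mtv, dtype=float)
    if scores.shape[0] != mtv.shape[0]:
        raise ValueError("scores and mtv must be paired per patient")
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    rows = []
    for j in range(scores.shape[1]):
        col = scores[:, j]
        degenerate = np.ptp(col) == 0 or np.ptp(mtv) == 0
        if degenerate:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(col, mtv)
        rows.append({"component": j + 1, "rho": rho, "p_value": p, "degenerate": degenerate})
    return pd.DataFrame(rows)
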