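"""Predictive and prognostic outcome models.

The predictive stage fits logistic models of the 1-year composite endpoint
(progression or death within 12 months) from whole-body MTV, per-category
radiomic principal components (PC1-3), and serum LDH — alone and combined —
evaluated by stratified 5-fold cross-validation with sensitivity,
specificity and rank-statistic AUC per fold.  All standardization and PC
projection is fit on training folds only.  The prognostic stage groups
patients at the median predicted probability of the PC model and compares
groups with Kaplan-Meier curves, the log-rank test, and a univariate Cox
model (hazard ratio with Wald 95% CI).

MTV enters models as log(MTV): burden spans orders of magnitude and the
planted synthetic hazard is linear in log-MTV; predicted ranks (hence AUC)
are insensitive to this monotone choice in a univariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features.manifest import category_of
from .reduction import CategoryPCA, CoVFilter

__all__ = [
    "auc_rank",
    "PCLogisticModel",
    "CVReport",
    "fit_logistic_cv",
    "risk_groups",
    "SurvivalReport",
    "km_logrank",
    "cox_hr",
    "stratify_by_median_mtv",
    "run_model_variant_suite",
    "category_columns",
]


def auc_rank(y_true, scores) -> float:
    """AUC as the Mann-Whitney concordant-pair fraction (ties credit 0.5)."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def category_columns(df: pd.DataFrame, modality: str, category: str) -> list[str]:
    """Feature columns of one modality (CT/PET prefix) and category."""
    prefix = f"{modality.upper()}_"
    cols = []
    for c in df.columns:
        if not c.startswith(prefix):
            continue
        try:
            if category_of(c) == category:
                cols.append(c)
        except KeyError:
            continue
    return cols


class PCLogisticModel(BaseEstimator, ClassifierMixin):
    """Logistic model over (optional) category PCs and direct covariates.

    ``pca_columns`` are reduced with a CoV filter + category PCA fitted on
    the training data, keeping scores 1..``n_pcs``; ``direct_columns``
    (e.g. log_mtv, ldh) are z-scored with training statistics.  The logistic
    fit is maximum likelihood; on non-convergence (separation) it falls back
    to a lightly ridge-penalized fit (penalty 1e-4) and flags it.
    """

    def __init__(
        self,
        pca_columns: tuple[str, ...] = (),
        direct_columns: tuple[str, ...] = (),
        n_pcs: int = 3,
        cov_threshold_pct: float = 3.0,
    ):
        self.pca_columns = pca_columns
        self.direct_columns = direct_columns
        self.n_pcs = n_pcs
        self.cov_threshold_pct = cov_threshold_pct

    def _design(self, X: pd.DataFrame, fit: bool) -> np.ndarray:
        blocks = []
        if len(self.pca_columns):
            sub = X.loc[:, list(self.pca_columns)]
            if fit:
                self.cov_filter_ = CoVFilter(self.cov_threshold_pct).fit(sub)
                filtered = self.cov_filter_.transform(sub)
                self.pca_ = CategoryPCA(max_components=max(self.n_pcs, 3)).fit(filtered)
            scores = self.pca_.transform(self.cov_filter_.transform(sub))
            blocks.append(scores[:, : self.n_pcs])
        if len(self.direct_columns):
            direct = X.loc[:, list(self.direct_columns)].to_numpy(dtype=float)
            if fit:
                self.direct_mean_ = direct.mean(axis=0)
                sd = direct.std(axis=0, ddof=1) if len(direct) > 1 else np.ones(direct.shape[1])
                self.direct_scale_ = np.where(sd > 1e-12, sd, 1.0)
            blocks.append((direct - self.direct_mean_) / self.direct_scale_)
        if not blocks:
            raise ValueError("model has no predictors")
        return np.hstack(blocks)

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("outcome has a single class")
        D = self._design(X, fit=True)
        self.ridge_fallback_ = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
            lr.fit(D, y)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                lr = LogisticRegression(penalty="l2", C=1.0 / 1e-4, solver="lbfgs", max_iter=5000)
                lr.fit(D, y)
                self.ridge_fallback_ = True
        self.logit_ = lr
        self.classes_ = lr.classes_
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "logit_")
        return self.logit_.predict_proba(self._design(X, fit=False))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class CVReport:
    """Per-fold and summary cross-validation metrics."""

    folds: pd.DataFrame  # fold, sensitivity, specificity, auc
    k: int
    seed: int

    def summary(self) -> dict[str, float]:
        out = {}
        for m in ("sensitivity", "specificity", "auc"):
            v = self.folds[m].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            out[f"{m}_mean"] = float(v.mean()) if v.size else np.nan
            out[f"{m}_min"] = float(v.min()) if v.size else np.nan
            out[f"{m}_max"] = float(v.max()) if v.size else np.nan
            # normal-approximation CI across folds, alongside the min-max band
            if v.size > 1:
                half = 1.96 * v.std(ddof=1) / np.sqrt(v.size)
                out[f"{m}_ci_lo"] = float(v.mean() - half)
                out[f"{m}_ci_hi"] = float(v.mean() + half)
        return out


def fit_logistic_cv(
    features: pd.DataFrame,
    outcome,
    model: PCLogisticModel,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold cross-validation of a PC-logistic model.

    Sensitivity/specificity at the given probability threshold; AUC by the
    rank statistic.  Requires at least k patients in each outcome class so
    every fold contains both classes.
    """
    y = np.asarray(outcome, dtype=int)
    n1, n0 = int(y.sum()), int((y == 0).sum())
    if min(n1, n0) < k:
        raise ValueError(f"need >= {k} patients per class, got {n1}/{n0}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        est = clone(model).fit(features.iloc[tr], y[tr])
        p = est.predict_proba(features.iloc[te])[:, 1]
        yt = y[te]
        pred = p >= threshold
        tp = int((pred & (yt == 1)).sum())
        tn = int((~pred & (yt == 0)).sum())
        sens = tp / max(int((yt == 1).sum()), 1)
        spec = tn / max(int((yt == 0).sum()), 1)
        rows.append(
            {
                "fold": fold,
                "sensitivity": sens,
                "specificity": spec,
                "auc": auc_rank(yt, p),
            }
        )
    return CVReport(folds=pd.DataFrame(rows), k=k, seed=seed)


def risk_groups(fitted: PCLogisticModel, features: pd.DataFrame) -> np.ndarray:
    """Binary risk grouping at the median predicted probability.

    Returns True for the high-risk half.  Identical probabilities for all
    patients are rejected (no grouping exists).
    """
    p = fitted.predict_proba(features)[:, 1]
    if np.ptp(p) < 1e-12:
        raise ValueError("all predicted probabilities identical; cannot form risk groups")
    return p > np.median(p)


@dataclass
class SurvivalReport:
    """KM curves per group plus log-rank test."""

    curves: pd.DataFrame  # group, time, survival, at_risk
    statistic: float
    p_value: float
    flagged: str = ""


def km_logrank(time, event, group) -> SurvivalReport:
    """Product-limit curves for two groups and the two-sample log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("need two nonempty groups")
    curves = []
    for g in (False, True):
        km = KaplanMeierFitter()
        km.fit(time[group == g], event[group == g])
        sf = km.survival_function_
        at_risk = km.event_table["at_risk"].reindex(sf.index).to_numpy()
        curves.append(
            pd.DataFrame(
                {
                    "group": "high" if g else "low",
                    "time": sf.index.to_numpy(),
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "at_risk": at_risk,
                }
            )
        )
    if not event.any():
        return SurvivalReport(pd.concat(curves, ignore_index=True), np.nan, np.nan,
                              flagged="no events; log-rank undefined")
    res = logrank_test(time[~group], time[group], event[~group], event[group])
    return SurvivalReport(
        curves=pd.concat(curves, ignore_index=True),
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def cox_hr(covariate, time, event) -> dict[str, float]:
    """Univariate Cox proportional-hazards fit: HR with Wald 95% CI."""
    df = pd.DataFrame(
        {"x": np.asarray(covariate, dtype=float), "t": np.asarray(time, dtype=float),
         "e": np.asarray(event, dtype=bool).astype(int)}
    )
    if df["e"].sum() < 1:
        raise ValueError("Cox model requires at least one event")
    cph = CoxPHFitter()
    flagged = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="t", event_col="e")
        except Exception as exc:  # monotone likelihood / separation
            return {"hr": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "p_value": np.nan,
                    "flagged": f"fit failed: {exc}"}
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return {
        "hr": float(np.exp(coef)),
        "ci_lo": float(np.exp(coef - 1.96 * se)),
        "ci_hi": float(np.exp(coef + 1.96 * se)),
        "p_value": float(cph.summary.loc["x", "p"]),
        "flagged": flagged,
    }


def stratify_by_median_mtv(cohort: pd.DataFrame, mtv_col: str = "mtv_ml"):
    """(low-burden, high-burden) sub-cohorts split at the median MTV.

    Median-valued patients go to the low-burden half; if every MTV is equal
    the high half is empty (with a warning).
    """
    mtv = cohort[mtv_col].to_numpy(dtype=float)
    med = float(np.median(mtv))
    low = cohort[mtv <= med]
    high = cohort[mtv > med]
    if len(high) == 0:
        warnings.warn("all MTV values at or below the median; high-burden stratum empty",
                      stacklevel=2)
    return low, high


# ---------------------------------------------------------------------------
# Model-variant suite (four predictor sets per sub-cohort x modality x category)

MODEL_VARIANTS = ("MTV", "PCs", "MTV+PCs", "MTV+PCs+LDH")


def _variant_model(variant: str, pc_cols: list[str]) -> PCLogisticModel:
    direct = {"MTV": ("log_mtv",), "PCs": (), "MTV+PCs": ("log_mtv",),
              "MTV+PCs+LDH": ("log_mtv", "ldh")}[variant]
    pca = () if variant == "MTV" else tuple(pc_cols)
    return PCLogisticModel(pca_columns=pca, direct_columns=direct)


def run_model_variant_suite(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    subcohorts=("Lymphatic", "Extranodal"),
    modalities=("CT", "PET"),
    categories=("Shape",),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated model variants plus risk-group survival tests.

    ``features``: one row per patient (the largest lesion of the relevant
    compartment) with CT_/PET_-prefixed feature columns and a ``subcohort``
    column; ``cohort``: patient_id, one_year_event, os/pfs time+event, ldh,
    mtv_ml.  For each sub-cohort x modality x category block the four
    predictor variants (MTV; PC1-3; MTV+PC1-3; MTV+PC1-3+LDH) are
    cross-validated, and the PC-model risk grouping is tested against OS and
    PFS by log-rank.  Missing sub-cohorts are skipped with a note row.
    """
    rows = []
    for sub in subcohorts:
        feats = features[features["subcohort"] == sub]
        if len(feats) == 0:
            rows.append({"subcohort": sub, "note": "missing sub-cohort; skipped"})
            continue
        merged = feats.merge(cohort, on="patient_id", how="inner",
                             suffixes=("", "_cohort"))
        merged = merged.reset_index(drop=True)
        merged["log_mtv"] = np.log(np.maximum(merged["mtv_ml"].to_numpy(dtype=float), 1e-6))
        y = merged["one_year_event"].to_numpy(dtype=int)
        for modality in modalities:
            for category in categories:
                pc_cols = category_columns(merged, modality, category)
                for variant in MODEL_VARIANTS:
                    model = _variant_model(variant, pc_cols)
                    try:
                        report = fit_logistic_cv(merged, y, model, k=k, seed=seed)
                    except ValueError as exc:
                        rows.append({"subcohort": sub, "modality": modality,
                                     "category": category, "variant": variant,
                                     "note": str(exc)})
                        continue
                    s = report.summary()
                    row = {"subcohort": sub, "modality": modality, "category": category,
                           "variant": variant, **s, "note": ""}
                    # prognosis: risk groups from the full-cohort PC-bearing fit
                    try:
                        full = _variant_model(variant, pc_cols).fit(merged, y)
                        grp = risk_groups(full, merged)
                        for endpoint in ("os", "pfs"):
                            rep = km_logrank(
                                merged[f"{endpoint}_time"], merged[f"{endpoint}_event"], grp
                            )
                            row[f"{endpoint}_logrank_p"] = rep.p_value
                    except ValueError as exc:
                        row["note"] = f"prognosis unavailable: {exc}"
                    rows.append(row)
    return pd.DataFrame(rows)
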