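"""Outcome models: AUC/log-rank/Cox oracles, CV hygiene, risk groups."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from petrad.models import (
    PCLogisticModel,
    auc_rank,
    cox_hr,
    fit_logistic_cv,
    km_logrank,
    risk_groups,
    run_model_variant_suite,
    stratify_by_median_mtv,
)


def auc_pair_oracle(y, s):
    """Brute-force concordant-pair fraction with 0.5 tie credit."""
    y = np.asarray(y, bool)
    s = np.asarray(s, float)
    num = den = 0.0
    for i in np.flatnonzero(y):
        for j in np.flatnonzero(~y):
            den += 1
            if s[i] > s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    return num / den


class TestAUC:
    def test_six_patient_separable_and_swap(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.6, 0.4, 0.2]
        assert auc_rank(y, s) == pytest.approx(1.0, abs=1e-12)
        s2 = [0.9, 0.8, 0.6, 0.7, 0.4, 0.2]  # swap one event/non-event pair
        assert auc_rank(y, s2) == pytest.approx(8.0 / 9.0, abs=1e-12)
        assert auc_rank(y, s2) == pytest.approx(auc_pair_oracle(y, s2), abs=1e-12)

    def test_matches_pair_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.random(20) < 0.4
            if y.all() or not y.any():
                continue
            s = rng.integers(0, 5, 20).astype(float)  # many ties
            assert auc_rank(y, s) == pytest.approx(auc_pair_oracle(y, s), abs=1e-10)


class TestLogisticCV:
    @staticmethod
    def toy_frame(n=400, seed=1, signal=0.0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(signal * x)))
        y = rng.random(n) < p
        df = pd.DataFrame({"x": x})
        return df, y.astype(int)

    def test_separable_predictor_gives_auc_one(self):
        df = pd.DataFrame({"x": np.r_[np.ones(10), np.zeros(10)]})
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        rep = fit_logistic_cv(df, y, PCLogisticModel(direct_columns=("x",)), seed=0)
        s = rep.summary()
        assert s["auc_mean"] == 1.0
        assert s["sensitivity_mean"] == 1.0
        assert s["specificity_mean"] == 1.0

    def test_null_predictor_auc_near_half(self):
        df, y = self.toy_frame(400, seed=2, signal=0.0)
        rep = fit_logistic_cv(df, y, PCLogisticModel(direct_columns=("x",)), seed=3)
        assert 0.4 <= rep.summary()["auc_mean"] <= 0.6

    def test_too_few_per_class_rejected(self):
        df = pd.DataFrame({"x": np.arange(8.0)})
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="per class"):
            fit_logistic_cv(df, y, PCLogisticModel(direct_columns=("x",)))

    def test_no_leakage_fold_models_ignore_test_rows(self):
        # manually refitting on the training rows only must reproduce the
        # fold predictions exactly (standardization/PCA fit on train only)
        rng = np.random.default_rng(4)
        n = 60
        df = pd.DataFrame(rng.standard_normal((n, 5)),
                          columns=[f"f{i}" for i in range(5)])
        y = (rng.random(n) < 0.5).astype(int)
        model = PCLogisticModel(pca_columns=tuple(df.columns), cov_threshold_pct=0.0)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
        for tr, te in skf.split(np.zeros(n), y):
            m1 = PCLogisticModel(pca_columns=tuple(df.columns),
                                 cov_threshold_pct=0.0).fit(df.iloc[tr], y[tr])
            p1 = m1.predict_proba(df.iloc[te])[:, 1]
            # corrupting the test rows must not change the fitted fold model
            df2 = df.copy()
            df2.iloc[te] = df2.iloc[te].to_numpy() * 100 + 7
            m2 = PCLogisticModel(pca_columns=tuple(df.columns),
                                 cov_threshold_pct=0.0).fit(df2.iloc[tr], y[tr])
            p2 = m2.predict_proba(df.iloc[te])[:, 1]
            assert np.allclose(p1, p2, atol=1e-10)


class TestRiskGroups:
    def test_median_split(self):
        probs = np.linspace(0.1, 0.9, 9)

        class Fake:
            def predict_proba(self, X):
                return np.c_[1 - probs, probs]

        grp = risk_groups(Fake(), pd.DataFrame(index=range(9)))
        assert grp.sum() == 4  # strictly above the median

    def test_monotone_predictor_matches_predictor_median_split(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        df = pd.DataFrame({"x": x})
        y = (x + 0.3 * rng.standard_normal(40) > 0).astype(int)
        m = PCLogisticModel(direct_columns=("x",)).fit(df, y)
        grp = risk_groups(m, df)
        assert np.array_equal(grp, x > np.median(x))

    def test_identical_probabilities_rejected(self):
        class Flat:
            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        with pytest.raises(ValueError):
            risk_groups(Flat(), pd.DataFrame(index=range(6)))


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([2.0, 4, 6, 8, 2, 4, 6, 8])
        e = np.ones(8, bool)
        g = np.r_[np.zeros(4, bool), np.ones(4, bool)]
        rep = km_logrank(t, e, g)
        assert rep.statistic == pytest.approx(0.0, abs=1e-10)
        assert rep.p_value == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_log_rank_table(self):
        # six subjects, times 1..6, alternating groups, all events
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, bool)
        g = np.array([0, 1, 0, 1, 0, 1], bool)
        # hand table: at each event time j, O1=group of dying subject,
        # E1 = n1_at_risk/n_at_risk, V = n1*n0/n^2 (single event, no ties)
        n1, n0 = 3, 3
        O1 = E1 = V = 0.0
        for time, grp in zip(t, g):
            n = n1 + n0
            O1 += grp
            E1 += n1 / n
            V += n1 * n0 / n**2
            if grp:
                n1 -= 1
            else:
                n0 -= 1
        stat_oracle = (O1 - E1) ** 2 / V
        rep = km_logrank(t, e, g)
        assert rep.statistic == pytest.approx(stat_oracle, abs=1e-10)

    def test_all_censored_curve_constant_one(self):
        t = np.array([3.0, 5, 7, 9])
        e = np.zeros(4, bool)
        g = np.array([0, 0, 1, 1], bool)
        rep = km_logrank(t, e, g)
        assert (rep.curves["survival"] == 1.0).all()
        assert rep.flagged.startswith("no events")

    def test_km_no_censoring_equals_empirical_survival(self):
        t = np.array([1.0, 2, 3, 4, 10, 12, 15, 20])
        e = np.ones(8, bool)
        g = np.r_[np.zeros(4, bool), np.ones(4, bool)]
        rep = km_logrank(t, e, g)
        low = rep.curves[rep.curves["group"] == "low"]
        sf = low.set_index("time")["survival"]
        assert sf.loc[2.0] == pytest.approx(0.5)  # 2 of 4 survive past t=2
        assert sf.loc[4.0] == pytest.approx(0.0)


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.standard_normal(n)
        t = rng.exponential(10.0, n)
        e = np.ones(n, bool)
        out = cox_hr(x, t, e)
        assert 0.9 <= out["hr"] <= 1.1
        assert out["ci_lo"] < out["hr"] < out["ci_hi"]

    def test_parameter_recovery_hr_in_ci(self):
        # simulate true HR 1.18 per unit; CI should contain it most of the time
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n = 1000
            x = rng.standard_normal(n)
            lam = 0.05 * np.exp(np.log(1.18) * x)
            t = rng.exponential(1 / lam)
            out = cox_hr(x, t, np.ones(n, bool))
            if out["ci_lo"] <= 1.18 <= out["ci_hi"]:
                hits += 1
        assert hits >= 9

    def test_matches_partial_likelihood_grid_oracle(self):
        # four subjects, no ties: solve the score equation independently
        x = np.array([0.0, 1.0, 0.5, 2.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, bool)

        def score(beta):
            # sum over event times of x_i - weighted mean of x over risk set
            order = np.argsort(t)
            s = 0.0
            for idx, i in enumerate(order):
                risk = order[idx:]
                w = np.exp(beta * x[risk])
                s += x[i] - np.sum(w * x[risk]) / np.sum(w)
            return s

        beta_oracle = brentq(score, -10, 10, xtol=1e-13)
        out = cox_hr(x, t, e)
        # lifelines' Newton iterations stop at a looser tolerance than brentq
        assert np.log(out["hr"]) == pytest.approx(beta_oracle, abs=1e-3)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_hr(np.arange(4.0), np.arange(1.0, 5.0), np.zeros(4, bool))


class TestStratifyByMedian:
    def test_one_to_ten(self):
        cohort = pd.DataFrame({"mtv_ml": np.arange(1.0, 11.0)})
        low, high = stratify_by_median_mtv(cohort)
        assert list(low["mtv_ml"]) == [1, 2, 3, 4, 5]
        assert list(high["mtv_ml"]) == [6, 7, 8, 9, 10]

    def test_all_equal_high_empty_with_warning(self):
        cohort = pd.DataFrame({"mtv_ml": np.full(6, 5.0)})
        with pytest.warns(UserWarning):
            low, high = stratify_by_median_mtv(cohort)
        assert len(low) == 6 and len(high) == 0

    def test_odd_n_distinct_sizes_51_50(self):
        cohort = pd.DataFrame({"mtv_ml": np.arange(101.0)})
        low, high = stratify_by_median_mtv(cohort)
        assert (len(low), len(high)) == (51, 50)


class TestModelVariantSuite:
    @staticmethod
    def synthetic_inputs(n=80, seed=0):
        from petrad.cohorts import simulate_feature_cohort
        from petrad.phantom import OutcomeModelSpec

        feats, cohort = simulate_feature_cohort(
            n, seed=seed, categories=("Shape",), modalities=("PET", "CT"),
            outcome=OutcomeModelSpec(beta_shape=4.0, seed=seed + 1),
        )
        return feats, cohort

    def test_four_rows_per_block_structure(self):
        feats, cohort = self.synthetic_inputs(80, seed=31)
        rep = run_model_variant_suite(feats, cohort, modalities=("PET",),
                               categories=("Shape",), seed=1)
        ok = rep[rep["note"] == ""] if "note" in rep else rep
        for sub in ("Lymphatic", "Extranodal"):
            block = rep[(rep.get("subcohort") == sub) & (rep.get("modality") == "PET")]
            assert len(block) == 4
            assert list(block["variant"]) == ["MTV", "PCs", "MTV+PCs", "MTV+PCs+LDH"]

    def test_missing_subcohort_skipped_with_note(self):
        feats, cohort = self.synthetic_inputs(40, seed=32)
        feats = feats[feats["subcohort"] == "Lymphatic"]
        rep = run_model_variant_suite(feats, cohort, modalities=("PET",), seed=1)
        note_rows = rep[rep["subcohort"] == "Extranodal"]
        assert len(note_rows) == 1
        assert "skipped" in note_rows.iloc[0]["note"]

    def test_combined_model_not_much_worse_than_singles(self):
        # planted shape effect: MTV+PCs should track the better single model
        from petrad.cohorts import simulate_feature_cohort
        from petrad.phantom import OutcomeModelSpec

        aucs = {"MTV": [], "PCs": [], "MTV+PCs": []}
        for seed in range(5):
            feats, cohort = simulate_feature_cohort(
                120, seed=200 + seed, categories=("Shape",), modalities=("PET",),
                outcome=OutcomeModelSpec(beta_shape=4.0, seed=300 + seed),
            )
            feats = feats.assign(subcohort="Extranodal")
            rep = run_model_variant_suite(feats, cohort, subcohorts=("Extranodal",),
                                   modalities=("PET",), categories=("Shape",),
                                   seed=seed)
            for v in aucs:
                row = rep[rep["variant"] == v]
                aucs[v].append(float(row["auc_mean"].iloc[0]))
        combined = np.mean(aucs["MTV+PCs"])
        assert combined >= np.mean(aucs["MTV"]) - 0.05
        assert combined >= np.mean(aucs["PCs"]) - 0.05
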