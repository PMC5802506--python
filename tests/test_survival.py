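"""Kaplan-Meier, log-rank, optimal cutpoint, Cox model, cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from mirelapse.cohorts import cohort_table
from mirelapse.survival import (
    cohort_summary,
    cox_fit,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
)
from mirelapse.synthetic import generate_survival_cohort


def surv_df(times, events, **cols):
    df = pd.DataFrame(
        {
            "patient": [f"p{i}" for i in range(len(times))],
            "time_months": times,
            "event": events,
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = km_estimate([3, 5, 7], [0, 0, 0])
        assert np.all(km([0, 1, 10]) == 1.0)

    def test_hand_product_limit_three_deaths(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km([0.5, 1.0, 2.5, 3.0]), [1, 2 / 3, 1 / 3, 0])

    def test_censoring_mixed_fixture_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = rng.exponential(10, 40).round(1)
        e = rng.integers(0, 2, 40)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0, t.max(), 25)
        np.testing.assert_allclose(
            km(grid), kmf.predict(grid).to_numpy(), atol=1e-10
        )

    def test_invariant_to_censoring_after_last_event(self):
        a = km_estimate([1, 2, 3, 9], [1, 1, 0, 0])
        b = km_estimate([1, 2, 3, 50], [1, 1, 0, 0])
        np.testing.assert_allclose(a.survival, b.survival)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        chi2, p = logrank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_tabulated_four_subject_fixture(self):
        # A: death t=1, censored t=4; B: deaths t=2, 3
        # O_A - E_A = -1/3, V = 13/18 -> chi2 = 2/13
        chi2, p = logrank_test([1, 4], [1, 0], [2, 3], [1, 1])
        assert chi2 == pytest.approx(2 / 13, abs=1e-12)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(10, 30), rng.exponential(20, 25)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        assert logrank_test(ta, ea, tb, eb) == pytest.approx(
            logrank_test(tb, eb, ta, ea)
        )

    def test_matches_lifelines_with_ties(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(2)
        ta = rng.integers(1, 10, 40).astype(float)
        tb = rng.integers(1, 10, 35).astype(float)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
        chi2, p = logrank_test(ta, ea, tb, eb)
        res = ll(ta, tb, ea, eb)
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-10)
        assert p == pytest.approx(res.p_value, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [1])

    def test_power_at_strong_hazard_ratio(self):
        # HR = 3 with 200 per arm: rejection rate comfortably above 80%
        rejections = 0
        n_sims = 200
        for s in range(n_sims):
            rng = np.random.default_rng(5000 + s)
            ta = rng.exponential(36, 200)
            tb = rng.exponential(12, 200)
            ca = rng.exponential(100, 200)
            cb = rng.exponential(100, 200)
            _, p = logrank_test(
                np.minimum(ta, ca), (ta <= ca).astype(int),
                np.minimum(tb, cb), (tb <= cb).astype(int),
            )
            rejections += p < 0.05
        assert rejections / n_sims >= 0.8


class TestOptimalCutpoint:
    def test_constant_biomarker_rejected(self):
        df = surv_df([1, 2, 3, 4], [1, 1, 0, 1])
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint([1.0, 1.0, 1.0, 1.0], df)

    def test_no_admissible_split_rejected(self):
        df = surv_df([1, 2, 3, 4], [1, 1, 0, 1])
        with pytest.raises(ValueError, match="group-size"):
            optimal_cutpoint([1, 1, 1, 2], df, min_group_frac=0.4)

    def test_equals_exhaustive_brute_force_on_30_patients(self):
        rng = np.random.default_rng(9)
        n = 30
        biomarker = rng.normal(size=n)
        base = np.where(biomarker > 0.3, 6.0, 24.0)
        times = rng.exponential(base)
        events = rng.random(n) < 0.8
        df = surv_df(times, events.astype(int))
        res = optimal_cutpoint(biomarker, df, min_group_frac=0.1)
        # oracle: every admissible split, log-rank from lifelines
        from lifelines.statistics import logrank_test as ll

        distinct = np.unique(biomarker)
        best_p, best_c = np.inf, None
        for c in (distinct[:-1] + distinct[1:]) / 2:
            hi = biomarker > c
            if hi.sum() < 3 or (~hi).sum() < 3:
                continue
            p = ll(times[~hi], times[hi], events[~hi], events[hi]).p_value
            if p < best_p:
                best_p, best_c = p, c
        assert res.cutpoint == pytest.approx(best_c, abs=1e-12)
        assert res.p_value == pytest.approx(best_p, rel=1e-9)
        assert res.p_value == res.profile["p"].min()
        assert res.n_low + res.n_high == n

    def test_group_size_constraint_respected(self):
        table, _ = generate_survival_cohort(n=120, seed=11)
        res = optimal_cutpoint(table["biomarker"].to_numpy(), table, min_group_frac=0.2)
        assert min(res.n_low, res.n_high) >= 24

    def test_high_means_strictly_above_cutoff(self):
        df = surv_df([5, 6, 1, 2, 7, 1], [1, 0, 1, 1, 0, 1])
        res = optimal_cutpoint([1, 1, 2, 2, 1, 2], df, min_group_frac=0.1)
        assert res.cutpoint == pytest.approx(1.5)
        assert res.n_high == 3


class TestCoxFit:
    def _no_ties_df(self):
        return surv_df(
            [1, 2, 3, 4, 5, 6, 7, 8],
            [1, 1, 1, 1, 1, 0, 1, 1],
            x=["a", "a", "a", "b", "b", "a", "b", "b"],
        )

    def test_matches_lifelines_without_ties(self):
        import lifelines

        df = self._no_ties_df()
        mine = cox_fit(df, ["x"], ties="efron")
        d2 = df.assign(xb=(df.x == "b").astype(float))[["time_months", "event", "xb"]]
        cph = lifelines.CoxPHFitter().fit(d2, "time_months", "event")
        assert mine.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert mine.se[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-6)
        # without ties Efron and Breslow coincide
        breslow = cox_fit(df, ["x"], ties="breslow")
        assert breslow.coef[0] == pytest.approx(mine.coef[0], abs=1e-10)

    def test_tied_fixture_matches_reference_survival_package(self):
        # coefficients/SEs frozen from R survival::coxph on this fixture
        df = surv_df(
            [1, 1, 2, 2, 3, 4, 4, 5, 6, 6],
            [1, 1, 1, 0, 1, 1, 1, 0, 1, 1],
            x=[str(v) for v in [0, 1, 1, 0, 1, 0, 1, 1, 0, 1]],
        )
        efron = cox_fit(df, ["x"], ties="efron")
        assert efron.coef[0] == pytest.approx(0.1447053406, abs=1e-6)
        assert efron.se[0] == pytest.approx(0.7349978806, abs=1e-6)
        breslow = cox_fit(df, ["x"], ties="breslow")
        assert breslow.coef[0] == pytest.approx(0.1634479196, abs=1e-6)
        assert breslow.se[0] == pytest.approx(0.7346675220, abs=1e-6)

    def test_rr_and_ci_are_consistent(self):
        fit = cox_fit(self._no_ties_df(), ["x"])
        assert fit.rr[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci95[0, 0] <= fit.rr[0] <= fit.ci95[0, 1]
        assert fit.rr[0] > 0

    def test_constant_covariate_rejected(self):
        df = self._no_ties_df().assign(x="a")
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_separation_is_flagged_not_silent(self):
        # group a all dies early, group b all censored late: no MLE
        df = surv_df(
            [1, 2, 3, 50, 60, 70],
            [1, 1, 1, 0, 0, 0],
            x=["a", "a", "a", "b", "b", "b"],
        )
        fit = cox_fit(df, ["x"])
        assert not fit.converged or fit.warnings

    def test_sign_agrees_with_km_ordering(self):
        table, _ = generate_survival_cohort(n=150, hazard_ratio=3.0, seed=12)
        grp = pd.Categorical(
            np.where(table["biomarker"] > 0.6745, "high", "low"),
            categories=["low", "high"],
        )
        df = table.assign(group=grp)
        fit = cox_fit(df, ["group"])
        km_low = km_estimate(
            df.loc[df.group == "low", "time_months"], df.loc[df.group == "low", "event"]
        )
        km_high = km_estimate(
            df.loc[df.group == "high", "time_months"], df.loc[df.group == "high", "event"]
        )
        t_ref = np.median(df["time_months"])
        assert (fit.coef[0] > 0) == (km_high(t_ref)[0] < km_low(t_ref)[0])

    def test_multivariate_with_categorical_ipi(self):
        table, _ = generate_survival_cohort(
            n=200, hazard_ratio=3.0, seed=13,
            covariates={"name": "IPI", "levels": ["0-2", "3-5"],
                        "probs": [0.6, 0.4], "hazard_ratios": [1.0, 2.0]},
        )
        grp = pd.Categorical(
            np.where(table["biomarker"] > 0.6745, "high", "low"),
            categories=["low", "high"],
        )
        fit = cox_fit(table.assign(group=grp), ["group", "IPI"])
        assert fit.converged
        assert len(fit.terms) == 2
        assert fit.rr[0] > 1.5  # biomarker effect direction recovered
        assert fit.rr[1] > 1.0  # IPI 3-5 adverse


class TestCohortSummary:
    def test_published_cohort_percentages(self):
        cgci = cohort_summary(cohort_table("CGCI"), group_by="subtype")
        row = cgci.query("characteristic == 'gender' and category == 'Male'").iloc[0]
        assert row["total_n"] == 61 and row["total_pct"] == 66
        assert row["GCB_n"] == 32 and row["GCB_pct"] == 63
        row = cgci.query("characteristic == 'IPI' and category == '0-2'").iloc[0]
        assert row["total_n"] == 62 and row["total_pct"] == 67

        llmpp = cohort_summary(cohort_table("LLMPP"), group_by="subtype")
        row = llmpp.query("characteristic == 'gender' and category == 'Male'").iloc[0]
        assert row["total_n"] == 134 and row["total_pct"] == 58

    def test_single_category_p_undefined(self):
        df = pd.DataFrame({"grp": ["a", "a", "b"], "char": ["x", "x", "x"]})
        out = cohort_summary(df, group_by="grp", characteristics=["char"])
        assert out.loc[0, "total_pct"] == 100
        assert np.isnan(out.loc[0, "p"])

    def test_association_p_matches_scipy_chi2(self):
        from scipy import stats

        df = cohort_table("CGCI")
        out = cohort_summary(df, group_by="subtype", characteristics=["stage"])
        ct = pd.crosstab(df["stage"], df["subtype"])
        expected = stats.chi2_contingency(ct.to_numpy(), correction=False)[1]
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)
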