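"""Median dichotomization, KM/log-rank, the Cox engine and the screen."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from pancontext.survival import (
    cox_fit,
    dichotomize_by_median,
    km_logrank,
    survival_screen,
)
from pancontext.synthetic import SyntheticSpec, generate_cohort


class TestDichotomize:
    def test_even_and_odd_tie_to_low(self):
        lab = dichotomize_by_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(lab) == ["low", "low", "high", "high"]
        lab3 = dichotomize_by_median(pd.Series([1.0, 2.0, 3.0]))
        assert list(lab3) == ["low", "low", "high"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_median_split(self, seed):
        rng = np.random.default_rng(seed)
        v = pd.Series(rng.integers(0, 10, 21).astype(float))
        lab = dichotomize_by_median(v)
        med = sorted(v)[len(v) // 2]
        expected = ["low" if x <= med else "high" for x in v]
        assert list(lab) == expected

    def test_constant_values_raise(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_by_median(pd.Series([2.0, 2.0, 2.0]))


def brute_force_logrank(times, events, groups):
    """Two-group log-rank statistic with hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    O_minus_E = 0.0
    V = 0.0
    for t in sorted(set(times[events].tolist())):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (g == labels[1])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (g == labels[1])).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [5.0, 8.0, 12.0, 5.0, 8.0, 12.0]
        e = [True] * 6
        g = ["a", "a", "a", "b", "b", "b"]
        res = km_logrank(t, e, g)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_six_subject_case_matches_hand_computation(self):
        t = [6.0, 7.0, 10.0, 15.0, 19.0, 25.0]
        e = [True] * 6
        g = ["a", "b", "a", "b", "a", "b"]
        res = km_logrank(t, e, g)
        assert res["statistic"] == pytest.approx(brute_force_logrank(t, e, g), rel=1e-9)

    def test_power_against_planted_hazard(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            grp = rng.integers(0, 2, n)
            lam = 0.01 * np.exp(np.log(2.0) * grp)
            t = rng.exponential(1 / lam)
            res = km_logrank(t, np.ones(n, bool), np.where(grp > 0, "hi", "lo"))
            rejections += res["p"] < 0.01
        assert rejections >= 19

    def test_empty_group_and_no_events_raise(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [True, True], ["a", "a"])
        with pytest.raises(ValueError, match="no events"):
            km_logrank([1.0, 2.0], [False, False], ["a", "b"])


class TestCoxEngine:
    def test_matches_lifelines_with_ties_and_censoring(self):
        rng = np.random.default_rng(1)
        n = 800
        g = rng.integers(0, 2, n).astype(float)
        x = rng.normal(size=n)
        lam = 0.002 * np.exp(0.6 * g - 0.3 * x)
        t = np.ceil(rng.exponential(1 / lam) / 30)  # monthly grid -> many ties
        c = rng.uniform(0, 60, n)
        obs = np.minimum(t, c)
        ev = t <= c
        fit = cox_fit(pd.DataFrame({"g": g, "x": x}), obs, ev)
        df = pd.DataFrame({"t": obs, "e": ev, "g": g, "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef_table["coef"], ref.params_, atol=1e-6)
        np.testing.assert_allclose(fit.coef_table["se"], ref.standard_errors_, atol=1e-6)

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 300
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1000 / (1 + g))
        fe = cox_fit(pd.DataFrame({"g": g}), t, np.ones(n, bool), ties="efron")
        fb = cox_fit(pd.DataFrame({"g": g}), t, np.ones(n, bool), ties="breslow")
        assert abs(np.log(fe.hr) - np.log(fb.hr)) < 1e-8

    def test_time_scaling_invariance(self, rng):
        n = 200
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(100 * (1 + 0.5 * g))
        e = rng.random(n) < 0.8
        f1 = cox_fit(pd.DataFrame({"g": g}), t, e)
        f2 = cox_fit(pd.DataFrame({"g": g}), t * 365.25, e)
        assert f1.hr == pytest.approx(f2.hr, rel=1e-9)
        assert f1.p == pytest.approx(f2.p, rel=1e-9)

    def test_null_covariate_hr_near_one(self, rng):
        n = 1000
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(100, n)
        fit = cox_fit(pd.DataFrame({"g": g}), t, np.ones(n, bool))
        assert 0.8 <= fit.hr <= 1.25

    def test_separation_flagged_not_raised(self):
        # group 0 all die first: monotone likelihood
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        g = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = cox_fit(pd.DataFrame({"g": g}), t, np.ones(6, bool))
        assert not fit.converged and np.isnan(fit.hr)

    def test_collinear_covariates_flagged(self, rng):
        n = 100
        x = rng.normal(size=n)
        fit = cox_fit(
            pd.DataFrame({"a": x, "b": 2 * x}), rng.exponential(10, n), np.ones(n, bool)
        )
        assert not fit.converged

    def test_invalid_ties_option(self, rng):
        with pytest.raises(ValueError, match="ties"):
            cox_fit(pd.DataFrame({"g": [1.0, 0.0]}), [1.0, 2.0], [True, True], ties="exact")


class TestSurvivalScreen:
    def test_gates_and_recovery_on_synthetic_cohort(self):
        spec = SyntheticSpec(
            cancer_types=[("PROT", 400), ("NULLCT", 60)],
            n_genes=30, planted_modules=[],
            survival_gamma={"PROT": -1.0, "NULLCT": 0.0},
            censoring_rate=0.2, covariate_missing=0.05, seed=21,
        )
        expr, ann = generate_cohort(spec)
        # starve NULLCT of events so its cells gate out
        idx = ann.cancer_type == "NULLCT"
        ann.loc[idx, "os_event"] = False
        ann.loc[idx.idxmax(), "os_event"] = True
        grid = survival_screen(expr, ann, "MAPT")
        prot_uni = grid[
            (grid.cancer_type == "PROT") & (grid.stratum == "ALL")
            & (grid.model == "univariate")
        ].iloc[0]
        assert prot_uni["eligible"] and prot_uni["hr"] < 1 and prot_uni["p"] < 0.05
        prot_multi = grid[
            (grid.cancer_type == "PROT") & (grid.stratum == "ALL")
            & (grid.model == "multivariate")
        ].iloc[0]
        assert prot_multi["eligible"] and prot_multi["hr"] < 1
        gated = grid[grid.cancer_type == "NULLCT"]
        assert not gated["eligible"].any()
        assert gated["hr"].isna().all()  # blanks, not zeros

    def test_covariate_availability_gate(self):
        spec = SyntheticSpec(
            cancer_types=[("CT", 120)], n_genes=20, planted_modules=[],
            survival_gamma=0.0, censoring_rate=0.1, seed=5,
        )
        expr, ann = generate_cohort(spec)
        # wipe covariates for all but 19 patients -> multivariate blank
        ann.loc[ann.index[19:], ["size_stage", "node_stage", "met_stage"]] = np.nan
        ann.loc[ann.index[19:], "aurka"] = np.nan
        grid = survival_screen(expr, ann, "MAPT", strata=("ALL",))
        multi = grid[grid.model == "multivariate"].iloc[0]
        uni = grid[grid.model == "univariate"].iloc[0]
        assert not multi["eligible"] and np.isnan(multi["hr"])
        assert uni["eligible"]
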