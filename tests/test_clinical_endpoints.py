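"""ROC, log-rank, cutpoint, Cox, Kaplan-Meier and Fisher response tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import fisher_2x2_oracle
from famscore import clinical_endpoints as ce


def surv_data(n=200, hr=1.0, seed=0, censor=0.0):
    """Two equal groups, exponential times, group 1 hazard multiplied by hr."""
    rng = np.random.default_rng(seed)
    group = np.repeat(["low", "high"], n // 2)
    lam = np.where(group == "high", hr, 1.0)
    t = rng.exponential(1.0 / lam)
    event = np.ones(n, dtype=int)
    if censor > 0:
        c = rng.uniform(0, np.quantile(t, 1 - censor) * 2, size=n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    return t, event, group


class TestRoc:
    def test_perfect_separation(self):
        res = ce.roc_auc([1, 2, 3, 10, 11, 12],
                         ["normal"] * 3 + ["tumor"] * 3)
        assert res.auc == 1.0
        assert (res.n_pos, res.n_neg) == (3, 3)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.4, "tumor", "normal")
        flipped = np.where(labels == "tumor", "normal", "tumor")
        a = ce.roc_auc(scores, labels).auc
        b = ce.roc_auc(scores, flipped).auc
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_auc_equals_trapezoid_of_curve_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(8, 60))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = np.where(rng.random(n) < 0.5, "tumor", "normal")
            if len(set(labels)) < 2:
                continue
            res = ce.roc_auc(scores, labels)
            fpr = 1 - res.curve["specificity"].to_numpy()
            tpr = res.curve["sensitivity"].to_numpy()
            assert res.auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_curve_endpoints(self):
        res = ce.roc_auc([1.0, 2.0, 3.0], ["normal", "tumor", "tumor"])
        first, last = res.curve.iloc[0], res.curve.iloc[-1]
        assert (first.sensitivity, first.specificity) == (0.0, 1.0)
        assert (last.sensitivity, last.specificity) == (1.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ce.roc_auc([1, 2], ["tumor", "tumor"])


class TestLogrank:
    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        t, e, g = surv_data(n=120, hr=1.8, seed=3, censor=0.2)
        ours = ce.logrank_test(t, e, g)
        ref = ll_logrank(t[g == "low"], t[g == "high"],
                         e[g == "low"], e[g == "high"])
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_identical_groups_statistic_near_zero(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(size=40)
        t2 = np.concatenate([t, t])
        e = np.ones(80, dtype=int)
        g = np.repeat(["a", "b"], 40)
        res = ce.logrank_test(t2, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_null_p_uniform(self):
        ps = []
        for seed in range(300):
            t, e, g = surv_data(n=60, hr=1.0, seed=seed, censor=0.2)
            ps.append(ce.logrank_test(t, e, g).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_at_hr_two(self):
        hits = 0
        for seed in range(30):
            t, e, g = surv_data(n=400, hr=2.0, seed=seed, censor=0.3)
            hits += ce.logrank_test(t, e, g).p_value < 0.05
        assert hits >= 27   # >= 90% power

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ce.logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCutpoint:
    def test_recovers_gap_between_risk_groups(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 200
            score = np.concatenate([rng.uniform(-2, -1, n // 2),
                                    rng.uniform(1, 2, n // 2)])
            lam = np.where(score > 0, 3.0, 1.0)   # HR 3 at score 0
            t = rng.exponential(1.0 / lam)
            res = ce.optimal_cutpoint(t, np.ones(n, dtype=int), score)
            # maximal selection may trade the exact gap split for one a few
            # samples inside a group's support edge; count the recovery if
            # the threshold lies in the gap or hugs its boundary
            hits += -1.2 <= res.cutpoint <= 1.2
        assert hits >= 0.95 * n_seeds

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ce.optimal_cutpoint([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0])

    def test_minprop_half_on_odd_n_infeasible(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 1, 1, 1, 1]
        s = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(ValueError, match="minprop"):
            ce.optimal_cutpoint(t, e, s, minprop=0.5)

    def test_minprop_keeps_both_sides_populated(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=100)
        t = rng.exponential(size=100)
        res = ce.optimal_cutpoint(t, np.ones(100, dtype=int), s, minprop=0.25)
        high = (s > res.cutpoint).sum()
        assert 25 <= high <= 75


class TestCox:
    def test_binary_hr_recovery(self):
        hrs = []
        for seed in range(20):
            t, e, g = surv_data(n=400, hr=2.0, seed=seed, censor=0.3)
            res = ce.cox_univariable(t, e, (np.asarray(g) == "high").astype(float))
            hrs.append(res.hr)
        assert np.mean(hrs) == pytest.approx(2.0, abs=0.2)

    def test_matches_lifelines_on_continuous_covariate(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))   # continuous: no ties
        e = np.ones(n, dtype=int)
        ours = ce.cox_univariable(t, e, x)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert np.log(ours.hr) == pytest.approx(ref.params_["x"], rel=1e-4)
        assert ours.cox_p == pytest.approx(
            ref.summary.loc["x", "p"], rel=1e-3)

    def test_classification_rule(self):
        t, e, g = surv_data(n=400, hr=3.0, seed=8, censor=0.2)
        x = (np.asarray(g) == "high").astype(float)
        assert ce.cox_univariable(t, e, x).classification == "risky"
        assert ce.cox_univariable(t, e, 1 - x).classification == "protective"

    def test_direction_agrees_with_logrank(self):
        for seed in range(10):
            t, e, g = surv_data(n=100, hr=1.7, seed=seed, censor=0.2)
            lr = ce.logrank_test(t, e, g)
            # z is signed for the lexicographically second level ("low");
            # the Cox coefficient of the matching 0/1 indicator must agree
            cox = ce.cox_univariable(t, e, (np.asarray(g) == "low").astype(float))
            assert (lr.z > 0) == (np.log(cox.hr) > 0)

    def test_separation_yields_sentinel_not_crash(self):
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        res = ce.cox_univariable(t, e, x)
        assert res.separated
        assert res.ci_high == np.inf
        assert res.classification == "ns"

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            ce.cox_univariable([1, 2, 3], [0, 0, 0], [1.0, 2.0, 3.0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ce.cox_univariable([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0])


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = ce.km_estimate([1, 2, 3], [0, 0, 0], ["g"] * 3)
        assert (km["survival"] == 1.0).all()

    def test_distinct_event_times_step_by_one_over_n(self):
        km = ce.km_estimate([1, 2, 3, 4], [1, 1, 1, 1], ["g"] * 4)
        surv = km.sort_values("time")["survival"].to_numpy()
        np.testing.assert_allclose(surv[-4:], [0.75, 0.5, 0.25, 0.0])

    def test_estimate_at_time_zero_is_one(self):
        km = ce.km_estimate([5, 6], [1, 1], ["g", "g"])
        assert km.loc[km["time"] == 0.0, "survival"].iloc[0] == 1.0


class TestResponse:
    def test_2x2_worked_example_matches_enumeration_oracle(self):
        groups = ["high"] * 10 + ["low"] * 10
        response = ["CR"] * 8 + ["PD"] * 2 + ["PR"] * 2 + ["SD"] * 8
        res = ce.response_association(groups, response)
        expected = fisher_2x2_oracle([[8, 2], [2, 8]])
        assert res.fisher_p == pytest.approx(expected, abs=1e-10)
        assert res.fisher_p == pytest.approx(0.0230, abs=5e-4)

    def test_identical_distributions_give_p_one(self):
        groups = ["high"] * 6 + ["low"] * 6
        response = ["CR", "CR", "CR", "PD", "PD", "PD"] * 2
        res = ce.response_association(groups, response)
        assert res.fisher_p == pytest.approx(1.0)

    def test_full_2x4_mode_matches_2x2_oracle_when_collapsed_structure(self):
        # with only two response levels present the 2x4 test reduces to 2x2
        groups = ["high"] * 10 + ["low"] * 10
        response = ["CR"] * 8 + ["PD"] * 2 + ["CR"] * 2 + ["PD"] * 8
        res = ce.response_association(groups, response, mode="full")
        assert res.fisher_p == pytest.approx(fisher_2x2_oracle([[8, 2], [2, 8]]),
                                             abs=1e-10)

    def test_2xk_oracle_agrees_with_scipy_on_random_2x2(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            table = rng.integers(0, 25, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = ce.fisher_exact_2xk(table)
            _, ref = stats.fisher_exact(table)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_planted_logistic_slope_detected(self):
        from famscore.synthetic_data import SimulationConfig, simulate_clinical

        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = pd.Series(rng.normal(size=200),
                          index=[f"S{i}" for i in range(200)])
            c = SimulationConfig.from_dict({
                "seed": seed,
                "response": {"logit_intercept": 0.0, "logit_slope": 1.5}})
            clin, _ = simulate_clinical(s, c)
            groups = np.where(s > s.median(), "high", "low")
            res = ce.response_association(groups, clin["response"])
            hits += res.fisher_p < 0.05
        assert hits >= 9

    def test_na_responses_dropped_and_empty_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty"):
            ce.response_association(["high", "high"], ["CR", "PD"])
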