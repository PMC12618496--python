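"""Evaluation battery versus hand computations and brute-force oracles."""
import numpy as np
import pytest
from scipy import stats

from mmsurv.metrics import (
    bootstrap_ci,
    bootstrap_compare,
    brier,
    c_index,
    calibration,
    chi2_counts,
    cohort_compare,
    decision_curve,
    iauc,
    ibs,
    km_estimate,
    km_survival_at,
    logrank,
    stratify,
    td_auc,
)


# ---------------------------------------------------------------------------
# C-index
# ---------------------------------------------------------------------------

def brute_force_c_index(risk, times, events):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if events[i] != 1 or not times[i] < times[j]:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den


class TestCIndex:
    def test_perfect_concordance(self):
        assert c_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_perfect_discordance(self):
        assert c_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        n = 200
        risk = rng.normal(size=n)
        times = rng.uniform(1, 50, size=n)
        events = rng.integers(0, 2, size=n)
        events[0] = 1
        expected = brute_force_c_index(risk, times, events)
        assert c_index(risk, times, events) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_ties_in_risk_credit_half(self):
        assert c_index([1, 1], [1, 2], [1, 1]) == 0.5

    def test_invariant_under_monotone_transform(self, rng):
        risk = rng.normal(size=100)
        times = rng.uniform(1, 50, size=100)
        events = rng.integers(0, 2, size=100)
        events[:5] = 1
        a = c_index(risk, times, events)
        b = c_index(np.exp(3 * risk) + 7, times, events)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            c_index([1, 2], [5, 5], [0, 0])


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

class TestKM:
    def test_three_uncensored_deaths(self):
        t, s, se = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(s, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_censoring_hand_oracle(self):
        # times (1, 2+, 3): S(1) = 2/3, S(3) = 2/3 * (1 - 1/1) = 0
        t, s, _ = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(t, [1, 3])
        np.testing.assert_allclose(s, [2 / 3, 0.0], atol=1e-12)

    def test_agrees_with_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.uniform(1, 40, size=150)
        events = rng.integers(0, 2, size=150)
        events[0] = 1
        t, s, _ = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        ours = [km_survival_at(times, events, q) for q in (5, 10, 20, 35)]
        theirs = [float(kmf.predict(q)) for q in (5, 10, 20, 35)]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 3, 5, 7, 9]
        e = [1, 1, 0, 1, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_agrees_with_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        ta = rng.exponential(10, 80)
        tb = rng.exponential(20, 70)
        ea = rng.integers(0, 2, 80)
        eb = rng.integers(0, 2, 70)
        ea[0] = eb[0] = 1
        chi2, p = logrank(ta, ea, tb, eb)
        ll = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-9)
        assert p == pytest.approx(ll.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1], [1])


# ---------------------------------------------------------------------------
# td-AUC / Brier (IPCW)
# ---------------------------------------------------------------------------

class TestTdAUC:
    def test_reduces_to_pairwise_auc_without_censoring(self, rng):
        n = 150
        times = rng.uniform(1, 40, size=n)
        events = np.ones(n, dtype=int)
        surv = rng.uniform(0.01, 0.99, size=n)
        for t in (10.0, 20.0, 30.0):
            cases = times <= t
            controls = ~cases
            if not cases.any() or not controls.any():
                continue
            risk = 1 - surv
            num = den = 0.0
            for rc in risk[cases]:
                for rk in risk[controls]:
                    den += 1
                    num += 1.0 if rc > rk else (0.5 if rc == rk else 0.0)
            assert td_auc(surv, times, events, t) == pytest.approx(num / den,
                                                                   abs=1e-12)

    def test_perfect_separation_gives_one(self):
        times = np.array([2.0, 4.0, 20.0, 30.0])
        events = np.ones(4, dtype=int)
        surv = np.array([0.1, 0.2, 0.9, 0.8])
        assert td_auc(surv, times, events, 10.0) == 1.0

    def test_horizon_beyond_followup_rejected(self):
        with pytest.raises(ValueError):
            td_auc([0.5, 0.5], [1.0, 2.0], [1, 1], 5.0)

    def test_iauc_of_constant_equals_constant(self, rng):
        # synthetic AUC(t) == a on a grid: integrate directly
        grid = np.arange(6.0, 37.0)
        a = 0.731
        vals = np.full(len(grid), a)
        assert np.trapezoid(vals, grid) / (grid[-1] - grid[0]) == pytest.approx(a)

    def test_iauc_grid_refinement_invariance_piecewise_linear(self):
        coarse = np.array([6.0, 18.0, 36.0])
        fine = np.arange(6.0, 37.0, 1.0)
        line = lambda g: 0.6 + 0.005 * (g - 6.0)
        i_coarse = np.trapezoid(line(coarse), coarse) / 30.0
        i_fine = np.trapezoid(line(fine), fine) / 30.0
        assert i_coarse == pytest.approx(i_fine, abs=1e-12)


def literal_ipcw_brier(surv, times, events, t):
    """Independent literal-summation Graf estimator."""
    n = len(times)
    cens_t = np.asarray(times, float)
    cens_e = 1 - np.asarray(events, int)

    def G(tq):
        s = 1.0
        for u in np.unique(cens_t[cens_e == 1]):
            if u > tq:
                break
            at_risk = np.sum(cens_t >= u)
            d = np.sum((cens_t == u) & (cens_e == 1))
            s *= 1 - d / at_risk
        return s

    def G_minus(tq):
        s = 1.0
        for u in np.unique(cens_t[cens_e == 1]):
            if u >= tq:
                break
            at_risk = np.sum(cens_t >= u)
            d = np.sum((cens_t == u) & (cens_e == 1))
            s *= 1 - d / at_risk
        return s

    total = 0.0
    for i in range(n):
        if times[i] <= t and events[i] == 1:
            total += surv[i] ** 2 / G_minus(times[i])
        elif times[i] > t:
            total += (1 - surv[i]) ** 2 / G(t)
    return total / n


class TestBrier:
    def test_oracle_predictions_score_zero(self):
        times = np.array([2.0, 4.0, 20.0, 30.0])
        events = np.ones(4, dtype=int)
        surv = np.array([0.0, 0.0, 1.0, 1.0])
        assert brier(surv, times, events, 10.0) == 0.0

    def test_constant_half_scores_quarter(self, rng):
        n = 100
        times = rng.uniform(1, 40, size=n)
        events = np.ones(n, dtype=int)
        surv = np.full(n, 0.5)
        for t in (10.0, 25.0):
            assert brier(surv, times, events, t) == pytest.approx(0.25,
                                                                  abs=1e-12)

    def test_matches_literal_ipcw_oracle_with_censoring(self, rng):
        n = 200
        times = rng.uniform(1, 40, size=n)
        events = rng.integers(0, 2, size=n)
        events[:3] = 1
        surv = rng.uniform(0, 1, size=n)
        for t in (10.0, 20.0):
            expected = literal_ipcw_brier(surv, times, events, t)
            assert brier(surv, times, events, t) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_ibs_normalized_trapezoid(self, rng):
        n = 60
        times = rng.uniform(1, 50, size=n)
        events = np.ones(n, dtype=int)
        grid = np.array([10.0, 20.0, 30.0])
        surv = np.tile(rng.uniform(0.2, 0.8, size=n)[:, None], (1, 3))
        bs = [brier(surv[:, k], times, events, t) for k, t in enumerate(grid)]
        expected = np.trapezoid(bs, grid) / 20.0
        assert ibs(surv, times, events, grid) == pytest.approx(expected,
                                                               abs=1e-12)


# ---------------------------------------------------------------------------
# Calibration and decision curves
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_perfectly_calibrated_recovery(self, rng):
        n = 5000
        p = rng.uniform(0.05, 0.95, size=n)
        y = rng.uniform(size=n) < p
        slope, intercept, ece, _ = calibration(p, y.astype(int))
        assert 0.9 <= slope <= 1.1
        assert -0.1 <= intercept <= 0.1
        assert ece < 0.05

    def test_extreme_correct_predictions_low_ece(self):
        p = np.array([0.01] * 50 + [0.99] * 50)
        y = np.array([0] * 50 + [1] * 50)
        _, _, ece, _ = calibration(p, y)
        assert ece < 0.02

    def test_doubled_logits_give_half_slope(self, rng):
        n = 8000
        logit = rng.normal(0, 1.5, size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
        p_over = 1 / (1 + np.exp(-2 * logit))  # overconfident doubling
        slope, _, _, _ = calibration(p_over, y)
        assert slope == pytest.approx(0.5, abs=0.06)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            calibration([0.2, 0.4], [1, 1])

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            calibration([0.0, 0.5], [0, 1])


class TestDecisionCurve:
    def test_treat_all_closed_form(self):
        rows = decision_curve([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0], [0.25])
        assert rows[0]["treat_all"] == pytest.approx(0.5 - 0.5 / 3, abs=1e-12)

    def test_treat_none_zero_everywhere(self):
        rows = decision_curve([0.9, 0.1], [1, 0], [0.1, 0.5, 0.9])
        assert all(r["treat_none"] == 0.0 for r in rows)

    def test_perfect_classifier_net_benefit_is_prevalence(self, rng):
        y = rng.integers(0, 2, size=200)
        r = y.astype(float)
        rows = decision_curve(r, y, [0.2, 0.5, 0.8])
        prev = y.mean()
        for row in rows:
            assert row["model"] == pytest.approx(prev, abs=1e-12)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], [1.0])


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

class TestStratify:
    def _two_clusters(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        high = rng.uniform(2, 3, size=n // 2)
        low = rng.uniform(-3, -2, size=n // 2)
        risk = np.concatenate([low, high])
        lam = np.where(risk > 0, 6.0, 30.0)
        times = lam * (-np.log(rng.uniform(size=n)))
        events = np.ones(n, dtype=int)
        return risk, np.maximum(times, 0.01), events

    @pytest.mark.parametrize("method", ["median", "logrank_optimal"])
    def test_recovers_planted_partition(self, method):
        risk, times, events = self._two_clusters()
        res = stratify(risk, times, events, method=method)
        assert -2.2 <= res.cutoff <= 2.2
        assert res.logrank_p < 1e-3
        agreement = np.mean(res.labels == (risk > 0).astype(int))
        assert agreement >= 0.98

    def test_median_split_halves(self, rng):
        n = 100
        risk = rng.normal(size=n)
        times = rng.uniform(1, 30, size=n)
        events = np.ones(n, dtype=int)
        res = stratify(risk, times, events, method="median")
        assert (res.labels == 1).sum() == 50

    def test_degenerate_risks_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            stratify(np.ones(50), np.arange(1, 51), np.ones(50, int))

    def test_permutation_p_not_anticonservative_under_null(self, rng):
        n = 120
        risk = rng.normal(size=n)
        times = rng.exponential(10, size=n) + 0.01
        events = np.ones(n, dtype=int)
        res = stratify(risk, times, events, method="logrank_optimal",
                       n_permutations=99, seed=1)
        # null data: permutation-corrected p should not be tiny
        assert res.permutation_p > 0.01

    def test_12mo_survival_reported_per_group(self):
        risk, times, events = self._two_clusters()
        res = stratify(risk, times, events)
        assert 0 <= res.survival_12mo["high"] < res.survival_12mo["low"] <= 1


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_constant_statistic_zero_width_ci(self):
        rep = bootstrap_ci(lambda x: 1.23, np.arange(50), n_boot=99, seed=0)
        assert rep.ci == (1.23, 1.23)

    def test_identical_predictions_p_one(self, rng):
        x = rng.normal(size=100)
        p = bootstrap_compare(lambda v: v.mean(), x, x, paired=True,
                              n_boot=99, seed=0)
        assert p == 1.0

    def test_p_lower_bounded(self, rng):
        a = rng.normal(5, 0.1, size=200)
        b = rng.normal(0, 0.1, size=200)
        p = bootstrap_compare(lambda v: v.mean(), a, b, paired=True,
                              n_boot=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_coverage_of_sample_mean(self):
        outer = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = outer.normal(size=500)
            rep = bootstrap_ci(lambda v: v.mean(), x, n_boot=199,
                               seed=int(outer.integers(1 << 31)))
            hits += rep.ci[0] <= 0.0 <= rep.ci[1]
        assert 0.90 <= hits / n_rep <= 0.99

    def test_failing_statistic_raises(self, rng):
        def fragile(x):
            # succeeds on the original sample (all unique), fails on nearly
            # every bootstrap resample (which contains duplicates)
            if np.unique(x).size < len(x):
                raise RuntimeError("duplicate rows")
            return x.mean()

        with pytest.raises(RuntimeError, match="replicates"):
            bootstrap_ci(fragile, rng.normal(size=20), n_boot=50, seed=0)


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

class TestCohortCompare:
    def test_four_cohort_sex_counts_p_value(self):
        # male/female counts across four cohorts; reference p = 0.502
        chi2, p = chi2_counts([[505, 52, 281, 299], [386, 32, 189, 200]])
        assert p == pytest.approx(0.502, abs=0.0005)
        assert chi2 == pytest.approx(2.3544, abs=1e-3)

    def test_identical_cohorts_p_one(self):
        import pandas as pd

        df = pd.DataFrame({"sex": ["male"] * 30 + ["female"] * 20,
                           "age": np.linspace(20, 80, 50)})
        res = cohort_compare({"a": df, "b": df.copy()})
        assert res["sex"]["p"] == pytest.approx(1.0)
        assert res["age"]["p"] == pytest.approx(1.0)

    def test_matches_textbook_2x2(self):
        # chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) without correction
        a, b, c, d = 10, 20, 30, 40
        chi2, p = chi2_counts([[a, b], [c, d]])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_anova_for_continuous(self, rng):
        import pandas as pd

        res = cohort_compare({
            "a": pd.DataFrame({"age": rng.normal(50, 10, 200)}),
            "b": pd.DataFrame({"age": rng.normal(60, 10, 200)}),
        })
        assert res["age"]["test"] == "anova"
        assert res["age"]["p"] < 1e-6

    def test_needs_two_cohorts(self):
        import pandas as pd

        with pytest.raises(ValueError):
            cohort_compare({"a": pd.DataFrame({"x": [1]})})
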