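"""Censoring-aware evaluation battery.

Discrimination (Harrell C-index, IPCW time-dependent AUC / IAUC),
calibration (IPCW Brier / IBS, calibration slope-intercept, ECE), decision
curve analysis, Kaplan-Meier / log-rank machinery, risk stratification, and
percentile-bootstrap inference.

Conventions: ``times`` are positive months, ``events`` is 1 for death and 0
for censoring, and ``risk`` is any score where larger = worse prognosis.
The td-AUC is the cumulative/dynamic IPCW variant; both it and the Brier
score reduce exactly to their unweighted forms when no subject is censored.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_GRID = np.arange(6.0, 37.0, 1.0)  # monthly, 6..36 months

__all__ = [
    "MetricReport",
    "StratificationResult",
    "c_index",
    "km_estimate",
    "km_survival_at",
    "logrank",
    "td_auc",
    "iauc",
    "brier",
    "ibs",
    "calibration",
    "decision_curve",
    "stratify",
    "bootstrap_ci",
    "bootstrap_compare",
    "cohort_compare",
]


@dataclass
class MetricReport:
    name: str
    point: float
    ci: tuple[float, float] = (np.nan, np.nan)
    n_boot: int = 0
    seed: int | None = None
    time_grid: np.ndarray | None = None

    def __post_init__(self):
        if self.n_boot > 0 and np.all(np.isfinite(self.ci)):
            lo, hi = self.ci
            if not (lo <= self.point + 1e-12 and self.point - 1e-12 <= hi):
                # percentile CIs can narrowly exclude the point estimate for
                # heavily discrete statistics; widen to honour the contract
                self.ci = (min(lo, self.point), max(hi, self.point))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "point": self.point,
            "ci": [self.ci[0], self.ci[1]],
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


@dataclass
class StratificationResult:
    cutoff: float
    method: str
    labels: np.ndarray  # 1 = high risk
    km_low: tuple[np.ndarray, np.ndarray, np.ndarray]
    km_high: tuple[np.ndarray, np.ndarray, np.ndarray]
    survival_12mo: dict[str, float]
    logrank_chi2: float
    logrank_p: float
    permutation_p: float | None = None


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def c_index(risk, times, events) -> float:
    """Harrell concordance: over comparable pairs (i with the earlier
    observed event), credit 1 for risk_i > risk_j, 0.5 for ties."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if not (len(risk) == len(times) == len(events)):
        raise ValueError("arrays must share length")
    order = np.argsort(times, kind="stable")
    risk, times, events = risk[order], times[order], events[order]
    n = len(times)
    num = den = 0.0
    # i indexes potential event subjects; comparable j have times_j > times_i
    for i in range(n):
        if events[i] != 1:
            continue
        later = times > times[i]
        den += later.sum()
        num += (risk[i] > risk[later]).sum() + 0.5 * (risk[i] == risk[later]).sum()
    if den == 0:
        raise ValueError("no comparable pairs for concordance")
    return float(num / den)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(times, events):
    """Product-limit estimator with Greenwood standard errors.

    Returns (event_times, survival, se) at the distinct event times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(times) == 0:
        raise ValueError("empty group")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    uniq = np.unique(times[events == 1])
    s = 1.0
    green = 0.0
    surv, ses = [], []
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            green += d / (at_risk * (at_risk - d))
        surv.append(s)
        ses.append(s * np.sqrt(green))
    return uniq, np.asarray(surv), np.asarray(ses)


def km_survival_at(times, events, t: float) -> float:
    """KM survival probability at time t (right-continuous step function)."""
    et, s, _ = km_estimate(times, events)
    past = et <= t
    return float(s[past][-1]) if past.any() else 1.0


def _censoring_km_at(times, events, t_query):
    """KM estimate of the censoring distribution G(t) = P(C > t), evaluated
    just *before* each query time (left-continuous, the Graf convention)."""
    times = np.asarray(times, float)
    cens = 1 - np.asarray(events, int)
    uniq = np.unique(times[cens == 1])
    s_vals = []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (cens == 1))
        s *= 1.0 - d / at_risk
        s_vals.append(s)
    s_vals = np.asarray(s_vals)

    def g_at(tq, before=False):
        if before:
            past = uniq < tq
        else:
            past = uniq <= tq
        return float(s_vals[past][-1]) if past.any() else 1.0

    return g_at


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi2, p) with chi2 ~ chi2(1)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("empty group in log-rank test")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    event_times = np.unique(all_t[all_e == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_t >= t
        n_tot = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        d_tot = ((all_t == t) & (all_e == 1)).sum()
        d_a = ((all_t == t) & (all_e == 1) & (grp == 0)).sum()
        if n_tot < 2:
            continue
        exp_a = d_tot * n_a / n_tot
        o_minus_e += d_a - exp_a
        var += (
            d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        )
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Time-dependent AUC and Brier score (IPCW)
# ---------------------------------------------------------------------------

def _check_horizon(times, t):
    if t > np.max(times):
        raise ValueError(f"horizon t={t} beyond last observed time {np.max(times)}")


def td_auc(surv_pred_at_t, times, events, t: float) -> float:
    """Cumulative/dynamic IPCW AUC at horizon t.

    Cases: observed events with time <= t.  Controls: subjects with
    time > t.  Cases are weighted by 1/G(T_i-); predicted risk at t is
    1 - S_i(t).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = 1.0 - np.asarray(surv_pred_at_t, float)
    _check_horizon(times, t)
    g_at = _censoring_km_at(times, events, None)
    cases = (times <= t) & (events == 1)
    controls = times > t
    if not cases.any() or not controls.any():
        raise ValueError("no cases or no controls at requested horizon")
    w = np.zeros(len(times))
    w[cases] = 1.0 / np.array([g_at(ti, before=True) for ti in times[cases]])
    num = 0.0
    den = 0.0
    r_cases, w_cases = risk[cases], w[cases]
    r_ctrl = risk[controls]
    for rc, wc in zip(r_cases, w_cases):
        num += wc * ((rc > r_ctrl).sum() + 0.5 * (rc == r_ctrl).sum())
        den += wc * len(r_ctrl)
    return float(num / den)


def iauc(surv_pred_matrix, times, events, grid=None) -> float:
    """Trapezoidal mean of AUC(t) over the grid.

    ``surv_pred_matrix`` has shape (n_subjects, n_gridpoints): S_i(t_k).
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, float)
    aucs = np.array(
        [td_auc(surv_pred_matrix[:, k], times, events, t) for k, t in enumerate(grid)]
    )
    return float(np.trapezoid(aucs, grid) / (grid[-1] - grid[0]))


def brier(surv_pred_at_t, times, events, t: float) -> float:
    """Graf IPCW Brier score at horizon t."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s_pred = np.asarray(surv_pred_at_t, float)
    _check_horizon(times, t)
    g_at = _censoring_km_at(times, events, None)
    n = len(times)
    total = 0.0
    for i in range(n):
        if times[i] <= t and events[i] == 1:
            total += s_pred[i] ** 2 / g_at(times[i], before=True)
        elif times[i] > t:
            total += (1.0 - s_pred[i]) ** 2 / g_at(t)
        # censored before t contributes 0
    return float(total / n)


def ibs(surv_pred_matrix, times, events, grid=None) -> float:
    """Integrated Brier score: trapezoidal integral over the grid divided by
    the grid span."""
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, float)
    bs = np.array(
        [brier(surv_pred_matrix[:, k], times, events, t) for k, t in enumerate(grid)]
    )
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


# ---------------------------------------------------------------------------
# Calibration and decision curves
# ---------------------------------------------------------------------------

def calibration(pred_prob_event, observed, n_bins: int = 10):
    """Calibration at a fixed horizon.

    Logistic regression of the observed binary outcome on the logit of the
    predicted event probability gives (slope, intercept); ECE is the
    prevalence-weighted mean |accuracy - confidence| over ``n_bins``
    equal-width probability bins.  Subjects censored before the horizon must
    already be excluded by the caller.

    Returns (slope, intercept, ece, curve) where curve is a list of
    (bin_mid, mean_pred, frac_observed, n).
    """
    import statsmodels.api as sm

    p = np.asarray(pred_prob_event, float)
    y = np.asarray(observed, int)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie in (0,1)")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate calibration fit: all outcomes identical")
    logit_p = np.log(p / (1 - p))
    X = sm.add_constant(logit_p)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ece = 0.0
    curve = []
    n = len(p)
    for b in range(n_bins):
        in_bin = (p >= edges[b]) & (p < edges[b + 1] if b < n_bins - 1 else p <= 1.0)
        if not in_bin.any():
            continue
        conf = p[in_bin].mean()
        acc = y[in_bin].mean()
        ece += (in_bin.sum() / n) * abs(acc - conf)
        curve.append(((edges[b] + edges[b + 1]) / 2, conf, acc, int(in_bin.sum())))
    return slope, intercept, float(ece), curve


def decision_curve(pred_risk, observed, thresholds):
    """Net benefit for the model, treat-all, and treat-none strategies.

    NB(p) = TP/n - FP/n * p/(1-p).
    """
    p_arr = np.asarray(thresholds, float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("thresholds must lie strictly inside (0,1)")
    r = np.asarray(pred_risk, float)
    y = np.asarray(observed, int)
    n = len(y)
    prevalence = y.mean()
    rows = []
    for p in p_arr:
        flagged = r >= p
        tp = np.sum(flagged & (y == 1)) / n
        fp = np.sum(flagged & (y == 0)) / n
        odds = p / (1 - p)
        rows.append(
            {
                "threshold": float(p),
                "model": float(tp - fp * odds),
                "treat_all": float(prevalence - (1 - prevalence) * odds),
                "treat_none": 0.0,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Risk stratification
# ---------------------------------------------------------------------------

def stratify(
    risk_scores,
    times,
    events,
    method: str = "logrank_optimal",
    min_group_frac: float = 0.10,
    n_permutations: int = 0,
    seed: int = 0,
) -> StratificationResult:
    """Split subjects into low/high risk at the median or at the log-rank
    optimal cutoff (scanned over the 10th-90th risk percentiles subject to a
    minimum group-size fraction)."""
    risk = np.asarray(risk_scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(risk)
    if n < 20:
        raise ValueError("stratification needs at least 20 subjects")
    if np.all(risk == risk[0]):
        raise ValueError("stratification impossible: all risk scores identical")

    def best_cutoff(r, t, e):
        candidates = np.unique(np.percentile(r, np.arange(10, 91)))
        best = (None, -np.inf)
        for c in candidates:
            hi = r > c
            if hi.sum() < min_group_frac * n or (~hi).sum() < min_group_frac * n:
                continue
            chi2, _ = logrank(t[~hi], e[~hi], t[hi], e[hi])
            if chi2 > best[1]:
                best = (c, chi2)
        if best[0] is None:
            raise ValueError("no admissible cutoff under group-size constraint")
        return best[0]

    if method == "median":
        cutoff = float(np.median(risk))
        if np.all(risk > cutoff) or np.all(risk <= cutoff):
            raise ValueError("degenerate median split")
    elif method == "logrank_optimal":
        cutoff = float(best_cutoff(risk, times, events))
    else:
        raise ValueError(f"unknown stratification method {method!r}")

    hi = risk > cutoff
    chi2, p = logrank(times[~hi], events[~hi], times[hi], events[hi])

    perm_p = None
    if n_permutations > 0 and method == "logrank_optimal":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            r_perm = rng.permutation(risk)
            try:
                c_perm = best_cutoff(r_perm, times, events)
            except ValueError:
                continue
            hi_p = r_perm > c_perm
            chi2_p, _ = logrank(times[~hi_p], events[~hi_p], times[hi_p], events[hi_p])
            exceed += chi2_p >= chi2
        perm_p = (exceed + 1) / (n_permutations + 1)

    s12 = {
        "low": km_survival_at(times[~hi], events[~hi], 12.0),
        "high": km_survival_at(times[hi], events[hi], 12.0),
    }
    return StratificationResult(
        cutoff=cutoff,
        method=method,
        labels=hi.astype(int),
        km_low=km_estimate(times[~hi], events[~hi]),
        km_high=km_estimate(times[hi], events[hi]),
        survival_12mo=s12,
        logrank_chi2=chi2,
        logrank_p=p,
        permutation_p=perm_p,
    )


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------

def bootstrap_ci(statistic, data, n_boot: int = 999, seed: int = 0,
                 name: str = "statistic") -> MetricReport:
    """Nonparametric percentile bootstrap CI of ``statistic(rows)``.

    ``data`` is indexable along axis 0 (array or tuple of aligned arrays).
    """
    arrays = data if isinstance(data, (tuple, list)) else (data,)
    arrays = [np.asarray(a) for a in arrays]
    n = len(arrays[0])
    point = float(statistic(*arrays))
    if n_boot == 0:
        return MetricReport(name, point, (point, point), 0, seed)
    rng = np.random.default_rng(seed)
    vals = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(float(statistic(*[a[idx] for a in arrays])))
        except Exception:  # noqa: BLE001 - statistic may fail on odd resamples
            failures += 1
    if failures > 0.05 * n_boot:
        raise RuntimeError(
            f"statistic failed on {failures}/{n_boot} bootstrap replicates"
        )
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return MetricReport(name, point, (float(lo), float(hi)), n_boot, seed)


def bootstrap_compare(
    statistic, data_a, data_b, paired: bool = True,
    n_boot: int = 999, seed: int = 0,
) -> float:
    """Bootstrap test of statistic(A) - statistic(B).

    Paired: resample subjects jointly; two-sample: independent resampling
    per cohort.  p = 2 * min(frac(delta <= 0), frac(delta >= 0)), bounded
    below by 1/(n_boot+1) and above by 1.
    """
    arrs_a = [np.asarray(a) for a in (data_a if isinstance(data_a, (tuple, list)) else (data_a,))]
    arrs_b = [np.asarray(b) for b in (data_b if isinstance(data_b, (tuple, list)) else (data_b,))]
    na, nb = len(arrs_a[0]), len(arrs_b[0])
    if paired and na != nb:
        raise ValueError("paired comparison requires aligned cohorts")
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        if paired:
            idx = rng.integers(0, na, size=na)
            sa = statistic(*[a[idx] for a in arrs_a])
            sb = statistic(*[a[idx] for a in arrs_b])
        else:
            ia = rng.integers(0, na, size=na)
            ib = rng.integers(0, nb, size=nb)
            sa = statistic(*[a[ia] for a in arrs_a])
            sb = statistic(*[a[ib] for a in arrs_b])
        deltas[b] = sa - sb
    frac_le = np.mean(deltas <= 0)
    frac_ge = np.mean(deltas >= 0)
    p = 2.0 * min(frac_le, frac_ge)
    return float(np.clip(p, 1.0 / (n_boot + 1), 1.0))


# ---------------------------------------------------------------------------
# Cohort comparison (baseline-characteristics table)
# ---------------------------------------------------------------------------

def cohort_compare(cohorts: dict[str, "object"], variables: list[str] | None = None):
    """Per-variable comparison across >= 2 cohorts.

    ``cohorts`` maps cohort name -> pandas DataFrame.  Categorical columns
    get a chi-square test on the category x cohort contingency table
    (missing values excluded); numeric columns get one-way ANOVA.
    Returns {variable: {"test": ..., "statistic": ..., "p": ...}}.
    """
    import pandas as pd

    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    frames = list(cohorts.values())
    if variables is None:
        variables = [c for c in frames[0].columns if all(c in f.columns for f in frames)]
    results = {}
    for var in variables:
        cols = [f[var].dropna() for f in frames]
        if all(pd.api.types.is_numeric_dtype(c) and c.nunique() > 10 for c in cols):
            stat, p = stats.f_oneway(*[np.asarray(c, float) for c in cols])
            if stat < 0 or np.isnan(p):  # rounding can drive F below 0
                stat, p = max(float(stat), 0.0), 1.0
            results[var] = {"test": "anova", "statistic": float(stat), "p": float(p)}
        else:
            cats = sorted(set().union(*[set(c.astype(str)) for c in cols]))
            table = np.array(
                [[np.sum(c.astype(str) == cat) for c in cols] for cat in cats]
            )
            table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            if table.shape[0] < 2 or table.shape[1] < 2:
                results[var] = {"test": "chi2", "statistic": np.nan, "p": np.nan}
                continue
            chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
            note = "zero expected cell count" if np.any(expected == 0) else ""
            results[var] = {
                "test": "chi2",
                "statistic": float(chi2),
                "p": float(p),
                "dof": int(dof),
                "note": note,
            }
    return results


def chi2_counts(table) -> tuple[float, float]:
    """Chi-square test on an explicit contingency table of counts."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)
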