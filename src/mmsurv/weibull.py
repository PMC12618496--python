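"""Weibull accelerated-failure-time mathematics.

Parameterization: scale lambda (months) and shape rho, stored on the log
scale.  S(t) = exp(-(t/lambda)^rho); hazard increases with t when rho > 1.
All likelihood terms are computed in log space so that nothing underflows
until (t/lambda)^rho itself overflows (~exp(700)).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gaussian_kde

# Clamp ranges for network outputs; keep NLL finite during training.
LOG_LAMBDA_RANGE = (np.log(0.1), np.log(600.0))
LOG_RHO_RANGE = (np.log(0.2), np.log(10.0))

__all__ = [
    "WeibullParams",
    "SurvivalCurve",
    "FitReport",
    "survival",
    "density",
    "nll",
    "nll_grad",
    "median_time",
    "risk_score",
    "predictive_samples",
    "survival_curve",
    "fit_parametric",
    "fit_weibull_direct",
]


@dataclass(frozen=True)
class WeibullParams:
    """Per-subject AFT parameters on the log scale.

    ``log_lambda``/``log_rho`` may be scalars or equal-length arrays (one
    entry per subject).
    """

    log_lambda: np.ndarray
    log_rho: np.ndarray

    def __post_init__(self):
        ll = np.asarray(self.log_lambda, dtype=float)
        lr = np.asarray(self.log_rho, dtype=float)
        if not (np.all(np.isfinite(ll)) and np.all(np.isfinite(lr))):
            raise ValueError("Weibull parameters must be finite")
        object.__setattr__(self, "log_lambda", ll)
        object.__setattr__(self, "log_rho", lr)

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.log_lambda)

    @property
    def rho(self) -> np.ndarray:
        return np.exp(self.log_rho)


@dataclass
class SurvivalCurve:
    """A personalized survival curve on a discrete time grid."""

    time_grid: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    density: np.ndarray
    time_ci_95: tuple[float, float] = (np.nan, np.nan)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time": self.time_grid,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "density": self.density,
            }
        ).to_csv(path, index=False)


@dataclass
class FitReport:
    family: str
    params: dict[str, float]
    log_likelihood: float
    aic: float
    max_km_deviation: float
    converged: bool = True
    notes: str = ""


def survival(params: WeibullParams, t) -> np.ndarray:
    """S(t) = exp(-(t/lambda)^rho), vectorized over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    lam, rho = params.lam, params.rho
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
    z = np.exp(np.clip(rho * (logt - params.log_lambda), -np.inf, 700.0))
    out = np.where(t > 0, np.exp(-z), 1.0)
    return out


def density(params: WeibullParams, t) -> np.ndarray:
    """Weibull pdf f(t) = (rho/lambda)(t/lambda)^(rho-1) S(t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    lam, rho = params.lam, params.rho
    tt = np.maximum(t, 1e-300)
    logf = (
        params.log_rho
        - params.log_lambda
        + (rho - 1.0) * (np.log(tt) - params.log_lambda)
        - (tt / lam) ** rho
    )
    return np.where(t > 0, np.exp(logf), np.where(rho == 1.0, 1.0 / lam, 0.0))


def _nll_terms(log_lambda, log_rho, times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be 0/1")
    rho = np.exp(log_rho)
    logt = np.log(times)
    log_z = rho * (logt - log_lambda)       # log (t/lambda)^rho
    z = np.exp(np.minimum(log_z, 700.0))
    # event: -log f = -(log rho - log lambda + (rho-1)(log t - log lambda)) + z
    log_f = log_rho - log_lambda + (rho - 1.0) * (logt - log_lambda) - z
    terms = np.where(events == 1, -log_f, z)
    return terms, rho, logt, log_z, z


def nll(params: WeibullParams, times, events) -> float:
    """Mean censored negative log-likelihood.

    Contribution -log f(t) for events, -log S(t) = (t/lambda)^rho for
    censored subjects.
    """
    terms, *_ = _nll_terms(params.log_lambda, params.log_rho, times, events)
    if not np.all(np.isfinite(terms)):
        bad = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise FloatingPointError(f"non-finite NLL contribution at subject index {bad}")
    return float(np.mean(terms))


def nll_grad(params: WeibullParams, times, events) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the mean NLL wrt (log_lambda, log_rho) per subject."""
    terms, rho, logt, log_z, z = _nll_terms(
        params.log_lambda, params.log_rho, times, events
    )
    events = np.asarray(events)
    n = times_len = len(np.atleast_1d(times))
    u = logt - params.log_lambda
    # d z / d log_lambda = -rho z ; d z / d log_rho = rho u z
    dz_dll = -rho * z
    dz_dlr = rho * u * z
    # event term: -(log rho - rho*log lambda + (rho-1) log t) + z
    d_event_dll = rho + dz_dll
    d_event_dlr = -(1.0 + rho * u) + dz_dlr
    g_ll = np.where(events == 1, d_event_dll, dz_dll) / n
    g_lr = np.where(events == 1, d_event_dlr, dz_dlr) / n
    return g_ll, g_lr


def median_time(params: WeibullParams) -> np.ndarray:
    """t solving S(t) = 1/2: lambda * (log 2)^(1/rho)."""
    return params.lam * np.log(2.0) ** (1.0 / params.rho)


def risk_score(params: WeibullParams, kind: str = "neg_median") -> np.ndarray:
    """Scalar risk: negative predicted median survival time (default), or
    ``neg_log_lambda``."""
    if kind == "neg_median":
        return -median_time(params)
    if kind == "neg_log_lambda":
        return -np.asarray(params.log_lambda)
    raise ValueError(f"unknown risk score kind: {kind!r}")


def predictive_samples(
    params: WeibullParams, n_draws: int = 10_000, seed: int = 0
):
    """Monte-Carlo survival-time draws for one subject.

    Inverse-CDF sampling t = lambda * (-log u)^(1/rho); the 95% interval is
    the [2.5th, 97.5th] empirical percentile pair, and a Gaussian KDE
    (Scott's rule) on the retained central draws gives the density.
    Returns (samples, (lo, hi), kde).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100 for a stable interval")
    lam = float(np.asarray(params.lam).reshape(()))
    rho = float(np.asarray(params.rho).reshape(()))
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n_draws)
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    samples = lam * (-np.log(u)) ** (1.0 / rho)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    retained = samples[(samples >= lo) & (samples <= hi)]
    spread = np.std(retained)
    if spread < 1e-12:  # degenerate (rho huge): KDE undefined, use a spike
        kde = None
    else:
        kde = gaussian_kde(retained)
    return samples, (float(lo), float(hi)), kde


def survival_curve(
    params: WeibullParams,
    time_grid=None,
    n_draws: int = 10_000,
    n_boot: int = 200,
    seed: int = 0,
) -> SurvivalCurve:
    """Personalized survival curve with Monte-Carlo uncertainty bands.

    The survival values are the analytic S(t); the CI band is the percentile
    envelope of empirical survival curves over bootstrap resamples of the
    Monte-Carlo draws (then widened, if needed, to contain S(t) pointwise).
    """
    if time_grid is None:
        time_grid = np.arange(0.0, 61.0, 1.0)
    time_grid = np.asarray(time_grid, dtype=float)
    samples, (lo_t, hi_t), kde = predictive_samples(params, n_draws, seed)
    s = survival(params, time_grid)
    rng = np.random.default_rng(seed + 1)
    boot = np.empty((n_boot, len(time_grid)))
    for b in range(n_boot):
        res = rng.choice(samples, size=len(samples), replace=True)
        boot[b] = (res[:, None] > time_grid[None, :]).mean(axis=0)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    lo = np.minimum(lo, s)
    hi = np.maximum(hi, s)
    if kde is None:
        dens = np.zeros_like(time_grid)
    else:
        dens = np.maximum(kde(time_grid), 0.0)
    return SurvivalCurve(time_grid, s, lo, hi, dens, (lo_t, hi_t))


# ---------------------------------------------------------------------------
# Parametric goodness-of-fit versus Kaplan-Meier
# ---------------------------------------------------------------------------

_FAMILIES = ("exponential", "weibull", "log-normal", "log-logistic",
             "generalized gamma")


def _km_curve(times, events):
    from .metrics import km_estimate

    return km_estimate(times, events)


def fit_parametric(times, events, family: str) -> FitReport:
    """Censored ML fit of one parametric family, benchmarked against the
    Kaplan-Meier estimate (max absolute deviation on the event-time grid)."""
    import lifelines

    family = family.lower()
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {_FAMILIES}")
    if int(np.sum(events)) < 10:
        raise ValueError("need at least 10 events for a parametric fit")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)

    fitters = {
        "exponential": lifelines.ExponentialFitter,
        "weibull": lifelines.WeibullFitter,
        "log-normal": lifelines.LogNormalFitter,
        "log-logistic": lifelines.LogLogisticFitter,
        "generalized gamma": lifelines.GeneralizedGammaFitter,
    }
    fitter = fitters[family]()
    converged, notes = True, ""
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(times, events)
        fitted = {k: float(v) for k, v in fitter.params_.items()}
        loglik = float(fitter.log_likelihood_)
        k = len(fitter.params_)
        aic = 2.0 * k - 2.0 * loglik
        event_times = np.unique(times[events == 1])
        km_t, km_s, _ = _km_curve(times, events)
        km_at = np.array([km_s[km_t <= t][-1] if np.any(km_t <= t) else 1.0
                          for t in event_times])
        model_at = np.asarray(
            fitter.survival_function_at_times(event_times)
        ).ravel()
        max_dev = float(np.max(np.abs(km_at - model_at)))
    except Exception as exc:  # noqa: BLE001 - non-convergence is reported, not raised
        return FitReport(family, {}, np.nan, np.nan, np.nan,
                         converged=False, notes=str(exc))
    return FitReport(family, fitted, loglik, aic, max_dev, converged, notes)


def fit_all_families(times, events) -> list[FitReport]:
    return [fit_parametric(times, events, f) for f in _FAMILIES]


def fit_weibull_direct(times, events, x0=(np.log(12.0), 0.0)) -> WeibullParams:
    """Direct MLE by numerically minimizing the mean censored NLL.

    Independent route from :func:`fit_parametric`; the two must agree.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)

    def objective(theta):
        p = WeibullParams(theta[0], theta[1])
        g_ll, g_lr = nll_grad(p, times, events)
        return nll(p, times, events), np.array([g_ll.sum(), g_lr.sum()])

    res = minimize(objective, np.asarray(x0, float), jac=True, method="L-BFGS-B")
    return WeibullParams(res.x[0], res.x[1])
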