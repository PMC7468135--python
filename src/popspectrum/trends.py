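"""Stage-1 estimation of population trends and fluctuations.

Each scaled abundance series is modelled as a Gaussian random walk with
drift observed with error:

    X_t = X_{t-1} + mu + eps_t,      eps_t ~ N(0, sigma^2)   (process noise)
    Y_t = X_t + F_t,                 F_t   ~ N(0, tau^2)     (observation error)

so that observed year-to-year increments follow

    Y_t = Y_{t-1} + mu + eps_t + F_t - F_{t-1}.

Conditioning on the first observation, the increment vector
D_i = Y_{t_i} - Y_{t_{i-1}} is multivariate normal with mean mu * Delta_i,
variance sigma^2 * Delta_i + 2 tau^2 and lag-1 covariance -tau^2 between
increments sharing a survey (an MA(1) signature that identifies observation
error separately from process noise).  Survey gaps enter only through the
Delta-scaled variances; no imputation is performed.

Parameters are estimated by restricted maximum likelihood (REML) on the
increments by default — the drift is profiled out analytically (GLS) and its
95% interval uses a t quantile with one degree of freedom per increment
minus one, the calibration recommended for exactly this random-walk trend
model.  Full maximum likelihood from multiple jittered starts with a
profile-likelihood (or Wald) interval is available via ``method='ml'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cholesky_banded, solve_banded

from .datasets import ScaledSeries

__all__ = [
    "StateSpaceParams",
    "TrendResults",
    "TrendEstimate",
    "StateSpaceTrendModel",
    "increment_loglik",
    "fit_state_space",
    "classify_trend",
    "fit_linear_trend",
    "fluctuation_metrics",
    "percent_change",
    "fit_many",
]

_LOG2PI = np.log(2.0 * np.pi)
#: chi^2(1) 0.95 quantile / 2 -- profile log-likelihood drop for a 95% CI
_PROFILE_DROP = stats.chi2.ppf(0.95, df=1) / 2.0


class InsufficientDataError(ValueError):
    """Series too short for the requested estimate."""


@dataclass
class StateSpaceParams:
    """Drift and variance components of the state-space model."""

    mu: float
    sigma2: float
    tau2: float

    def __post_init__(self):
        if self.sigma2 < 0 or self.tau2 < 0:
            raise ValueError("variance components must be non-negative")


def _increments(series: ScaledSeries):
    if series.n_obs < 2:
        raise InsufficientDataError(
            f"{series.series_id}: need >= 2 observations, have {series.n_obs}"
        )
    d = np.diff(series.values)
    delta = np.diff(series.years).astype(float)
    if np.any(delta < 1):
        raise ValueError(f"{series.series_id}: years not strictly increasing")
    return d, delta


def _banded_loglik(d, delta, mu, sigma2, tau2):
    """Log-density of the increment vector via a banded Cholesky factor.

    The covariance is tridiagonal: diag sigma2*Delta + 2*tau2, off-diagonal
    -tau2.  O(n) and exact.
    """
    n = d.size
    diag = sigma2 * delta + 2.0 * tau2
    if np.any(diag <= 0):
        return -np.inf
    resid = d - mu * delta
    if tau2 == 0.0:
        # independent increments
        return -0.5 * np.sum(resid**2 / diag + np.log(diag) + _LOG2PI)
    ab = np.zeros((2, n))
    ab[0] = diag
    ab[1, : n - 1] = -tau2
    try:
        chol = cholesky_banded(ab, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(chol[0]))
    # solve L z = resid by forward substitution on the banded factor
    z = solve_banded((1, 0), chol, resid)
    return -0.5 * (z @ z + logdet + n * _LOG2PI)


def increment_loglik(series: ScaledSeries, params: StateSpaceParams) -> float:
    """Exact log-likelihood of the observed increments, conditioning on the
    first observation.

    Raises
    ------
    InsufficientDataError
        if the series has fewer than two observations.
    """
    d, delta = _increments(series)
    return float(_banded_loglik(d, delta, params.mu, params.sigma2, params.tau2))


@dataclass
class TrendResults:
    """Stage-1 results for one series: parameter estimates, the 95% interval
    on the trend, its classification, and the fluctuation metrics.

    ``classification`` is 'decline' when the interval lies entirely below
    zero, 'increase' when entirely above, else 'no_net_change'.
    """

    series_id: str
    params: StateSpaceParams
    ci95_mu: tuple[float, float]
    loglik: float
    converged: bool
    ci_method: str = "profile"
    slope_lm: float = np.nan
    se_slope: float = np.nan
    p_slope: float = np.nan
    sd_raw: float = np.nan
    latent_states: np.ndarray | None = field(default=None, repr=False)

    @property
    def half_ci(self) -> float:
        lo, hi = self.ci95_mu
        return (hi - lo) / 2.0

    @property
    def classification(self) -> str:
        return classify_trend(self)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Series {self.series_id}  (state-space trend fit)",
            f"  mu      = {p.mu: .5f}   95% CI ({self.ci95_mu[0]: .5f}, "
            f"{self.ci95_mu[1]: .5f})  [{self.ci_method}]",
            f"  sigma^2 = {p.sigma2: .6f}   tau^2 = {p.tau2: .6f}",
            f"  loglik  = {self.loglik: .4f}   converged = {self.converged}",
            f"  classification: {self.classification}",
        ]
        return "\n".join(lines)


#: alias used throughout the pipeline tables
TrendEstimate = TrendResults


def classify_trend(est: TrendResults) -> str:
    """'decline' iff the 95% interval is below zero, 'increase' iff above,
    else 'no_net_change'."""
    lo, hi = est.ci95_mu
    if hi < 0:
        return "decline"
    if lo > 0:
        return "increase"
    return "no_net_change"


class StateSpaceTrendModel:
    """Maximum-likelihood state-space trend model for one scaled series.

    Parameters
    ----------
    series : ScaledSeries
        The within-population rescaled abundance record.

    Examples
    --------
    >>> res = StateSpaceTrendModel(scaled).fit(seed=1)
    >>> res.params.mu, res.ci95_mu
    """

    _SIGMA2_FLOOR = 1e-12

    def __init__(self, series: ScaledSeries):
        self.series = series
        if not series.constant_flag:
            self._d, self._delta = _increments(series)

    def loglik(self, mu: float, sigma2: float, tau2: float) -> float:
        return float(_banded_loglik(self._d, self._delta, mu, sigma2, tau2))

    # -- REML ---------------------------------------------------------------
    def _gls_mu(self, sigma2, tau2):
        """GLS drift estimate and its standard error at fixed variances."""
        d, delta = self._d, self._delta
        q = d.size
        ab = np.zeros((2, q))
        ab[0] = sigma2 * delta + 2.0 * tau2
        ab[1, : q - 1] = -tau2
        chol = cholesky_banded(ab, lower=True)
        zD = solve_banded((1, 0), chol, d)
        zX = solve_banded((1, 0), chol, delta)
        xtx = zX @ zX
        mu = (zX @ zD) / xtx
        logdet = 2.0 * np.sum(np.log(chol[0]))
        resid = zD - mu * zX
        return mu, 1.0 / np.sqrt(xtx), logdet, float(resid @ resid), xtx

    def _neg_restricted_ll(self, p):
        sigma2, tau2 = p
        if sigma2 <= 0 or tau2 < 0:
            return np.inf
        try:
            _, _, logdet, rss, xtx = self._gls_mu(sigma2, tau2)
        except (np.linalg.LinAlgError, FloatingPointError):
            return np.inf
        return 0.5 * (logdet + np.log(xtx) + rss)

    def _fit_reml(self) -> tuple[StateSpaceParams, float, float]:
        """REML point estimates plus the GLS (mu, se)."""
        d, delta = self._d, self._delta
        mu0 = d.sum() / delta.sum()
        v = float(np.var((d - mu0 * delta) / np.sqrt(delta)))
        if v <= 1e-14:  # exact linear series
            return StateSpaceParams(float(mu0), 0.0, 0.0), float(mu0), 0.0
        best, bestf = None, np.inf
        for x0 in ((0.8 * v, 0.1 * v), (0.5 * v, 0.25 * v),
                   (0.1 * v, 0.45 * v), (v, 1e-8 * v)):
            res = optimize.minimize(
                self._neg_restricted_ll, x0, method="Nelder-Mead",
                options=dict(xatol=1e-12, fatol=1e-12, maxiter=600))
            if res.fun < bestf:
                best, bestf = res, res.fun
        sigma2 = max(float(best.x[0]), 0.0)
        tau2 = max(float(best.x[1]), 0.0)
        mu, se, *_ = self._gls_mu(max(sigma2, 1e-12), tau2)
        return StateSpaceParams(float(mu), sigma2, tau2), float(mu), float(se)

    # -- starting values ---------------------------------------------------
    def _moment_start(self):
        d, delta = self._d, self._delta
        mu0 = d.sum() / delta.sum()
        r = d - mu0 * delta
        v = max(np.var(r / np.sqrt(delta)), 1e-8)
        # lag-1 autocovariance of increments is -tau^2 under the model
        tau0 = 0.0
        if d.size >= 3:
            c1 = np.mean(r[:-1] * r[1:])
            tau0 = max(-c1, 0.0)
        tau0 = min(tau0, 0.45 * v)
        sig0 = max(v - 2.0 * tau0, 1e-8)
        return mu0, sig0, tau0

    def _fit_at(self, start, fix_mu=None, fix_tau2=None):
        lo = self._SIGMA2_FLOOR

        if fix_mu is None and fix_tau2 is None:
            def nll(p):
                return -_banded_loglik(self._d, self._delta, p[0], p[1], p[2])
            x0 = np.asarray(start)
            bounds = [(None, None), (lo, None), (0.0, None)]
        elif fix_mu is not None:
            def nll(p):
                return -_banded_loglik(self._d, self._delta, fix_mu, p[0], p[1])
            x0 = np.asarray(start[1:])
            bounds = [(lo, None), (0.0, None)]
        else:
            def nll(p):
                return -_banded_loglik(self._d, self._delta, p[0], p[1], fix_tau2)
            x0 = np.asarray(start[:2])
            bounds = [(None, None), (lo, None)]
        return optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)

    def fit(self, method: str = "reml", starts: int = 8, seed: int | None = 0,
            ci_method: str | None = None, fix_tau2: float | None = None,
            smooth: bool = False) -> TrendResults:
        """Fit the state-space model.

        ``method='reml'`` (default): restricted ML for the variances, GLS for
        the drift, t-quantile interval (better-calibrated variances on short
        series).  ``method='ml'``: full ML from ``starts`` jittered initial
        values with a profile-likelihood interval (``ci_method`` may force
        'wald'); ``fix_tau2`` pins the observation-error variance.

        A constant (flagged) series returns mu = 0 with zero variances and a
        degenerate interval.  Non-convergence from every start is reported on
        the result (``converged=False``), never silently.
        """
        s = self.series
        if s.constant_flag:
            return TrendResults(
                s.series_id, StateSpaceParams(0.0, 0.0, 0.0), (0.0, 0.0),
                0.0, True, ci_method="degenerate",
            )
        if method == "reml":
            params, mu, se = self._fit_reml()
            q = self._d.size
            tq = stats.t.ppf(0.975, max(q - 1, 1))
            ci = (mu - tq * se, mu + tq * se)
            ll = float(_banded_loglik(self._d, self._delta, params.mu,
                                      max(params.sigma2, 1e-300), params.tau2))
            out = TrendResults(s.series_id, params, ci, ll, True,
                               ci_method="reml-t")
            if smooth:
                out.latent_states = self._smooth(params)
            return out
        if method != "ml":
            raise ValueError(f"unknown method: {method!r}")
        rng = np.random.default_rng(seed)
        mu0, sig0, tau0 = self._moment_start()
        base = np.array([mu0, sig0, max(tau0, 0.1 * sig0)])
        best, best_nll = None, np.inf
        any_ok = False
        for i in range(starts):
            if i == 0:
                x0 = base
            else:
                jit = rng.normal(size=3)
                x0 = np.array([
                    base[0] + 0.5 * abs(base[0] + 0.01) * jit[0],
                    base[1] * np.exp(jit[1]),
                    base[2] * np.exp(jit[2]),
                ])
            res = self._fit_at(x0, fix_tau2=fix_tau2)
            if np.isfinite(res.fun) and res.fun < best_nll:
                best, best_nll = res, res.fun
                any_ok = any_ok or res.success
        if fix_tau2 is None:
            mu, sigma2, tau2 = best.x
        else:
            (mu, sigma2), tau2 = best.x, fix_tau2
        sigma2 = max(sigma2 - self._SIGMA2_FLOOR, 0.0) if sigma2 <= 2 * self._SIGMA2_FLOOR else sigma2
        params = StateSpaceParams(float(mu), float(sigma2), float(tau2))
        ll = -best_nll
        ci, used = self._ci_mu(params, ll, method=ci_method or "profile")
        out = TrendResults(s.series_id, params, ci, float(ll), bool(any_ok),
                           ci_method=used)
        if smooth:
            out.latent_states = self._smooth(params)
        return out

    # -- confidence interval on mu ----------------------------------------
    def _wald_se(self, params) -> float:
        # numerical curvature of the profile in mu (variances re-maximised)
        mu = params.mu
        h = max(1e-4, 1e-3 * abs(mu))
        start = (mu, max(params.sigma2, 1e-8), params.tau2)

        def prof(m):
            r = self._fit_at(start, fix_mu=m)
            return -r.fun

        l0 = prof(mu)
        lp, lm = prof(mu + h), prof(mu - h)
        curv = -(lp - 2 * l0 + lm) / h**2
        if curv <= 0 or not np.isfinite(curv):
            # fall back to observed-information of mu alone
            d, delta = self._d, self._delta
            curv = np.sum(delta**2 / (params.sigma2 * delta + 2 * params.tau2 + 1e-12))
        return 1.0 / np.sqrt(curv)

    def _ci_mu(self, params, llmax, method="profile"):
        se = self._wald_se(params)
        wald = (params.mu - 1.96 * se, params.mu + 1.96 * se)
        if method != "profile":
            return wald, "wald"
        start = (params.mu, max(params.sigma2, 1e-8), params.tau2)
        target = llmax - _PROFILE_DROP

        def g(m):
            return -self._fit_at(start, fix_mu=m).fun - target

        def bracket(direction):
            step = max(se, 1e-6)
            a = params.mu
            for _ in range(40):
                b = a + direction * step
                if g(b) < 0:
                    return a, b
                a = b
                step *= 1.6
            return None

        try:
            lo_br = bracket(-1.0)
            hi_br = bracket(+1.0)
            if lo_br is None or hi_br is None:
                return wald, "wald"
            lo = optimize.brentq(g, lo_br[1], lo_br[0], xtol=1e-7)
            hi = optimize.brentq(g, hi_br[0], hi_br[1], xtol=1e-7)
            return (float(lo), float(hi)), "profile"
        except Exception:
            return wald, "wald"

    # -- latent-state smoothing (diagnostic) -------------------------------
    def _smooth(self, params) -> np.ndarray:
        """Posterior mean of the latent states X at the survey years given
        the fitted parameters (joint-Gaussian conditioning; O(n^3) but n is
        a series length)."""
        s = self.series
        t = s.years.astype(float)
        y = s.values
        n = t.size
        # covariance of X (random walk from X_1, conditioning on X_1 ~ diffuse:
        # work with increments relative to first observation)
        tt = np.minimum.outer(t - t[0], t - t[0])
        Sx = params.sigma2 * tt
        Sy = Sx + params.tau2 * np.eye(n)
        mean_x = y[0] + params.mu * (t - t[0])
        try:
            w = np.linalg.solve(Sy + 1e-10 * np.eye(n), y - mean_x)
        except np.linalg.LinAlgError:
            return mean_x
        return mean_x + Sx @ w


def fit_state_space(series: ScaledSeries, method: str = "reml",
                    starts: int = 8, seed: int | None = 0,
                    ci_method: str | None = None) -> TrendResults:
    """Convenience wrapper: build a StateSpaceTrendModel and fit it, then
    attach the linear-trend comparison fit and fluctuation inputs."""
    res = StateSpaceTrendModel(series).fit(method=method, starts=starts,
                                           seed=seed, ci_method=ci_method)
    res.sd_raw = float(np.std(series.values, ddof=1)) if series.n_obs > 1 else 0.0
    if series.n_obs >= 2 and not series.constant_flag:
        res.slope_lm, res.se_slope, res.p_slope = fit_linear_trend(series)
    elif series.constant_flag:
        res.slope_lm, res.se_slope, res.p_slope = 0.0, 0.0, 1.0
    return res


def fit_linear_trend(series: ScaledSeries) -> tuple[float, float, float]:
    """OLS slope of scaled abundance on calendar year, with its standard
    error and two-sided t-test p-value."""
    if series.n_obs < 2:
        raise InsufficientDataError(
            f"{series.series_id}: need >= 2 observations for a slope"
        )
    lr = stats.linregress(series.years.astype(float), series.values)
    return float(lr.slope), float(lr.stderr), float(lr.pvalue)


def fluctuation_metrics(series: ScaledSeries, est: TrendResults) -> np.ndarray:
    """The five per-series variability metrics, in their canonical order:

    1. standard error of the OLS slope of abundance vs year;
    2. half of the 95% interval around mu;
    3. the same half-interval augmented by the series' observation-error
       variance (the measurement-error convention used for weighting in
       stage 2: the squared tau^2 adds to the squared standard error);
    4. process noise sigma^2;
    5. sample standard deviation of the scaled series.

    Across a dataset each metric is z-scaled before second-stage modelling.
    """
    se_slope = est.se_slope
    if not np.isfinite(se_slope):
        se_slope = fit_linear_trend(series)[1]
    half = est.half_ci
    se_mu = half / 1.96
    half_weighted = 1.96 * np.sqrt(se_mu**2 + est.params.tau2**2)
    sd_raw = est.sd_raw
    if not np.isfinite(sd_raw):
        sd_raw = float(np.std(series.values, ddof=1))
    return np.array([se_slope, half, half_weighted, est.params.sigma2, sd_raw])


def percent_change(first: float, last: float) -> float:
    """Percent change from the first to the last survey: 100*(last-first)/first.

    Raises
    ------
    ValueError
        when the first abundance is zero (relative change undefined).
    """
    if first == 0:
        raise ValueError("percent change undefined for a zero starting abundance")
    return 100.0 * (last - first) / first


def fit_many(scaled: list[ScaledSeries], method: str = "reml",
             starts: int = 8, seed: int | None = 0):
    """Fit every series; returns (list of TrendResults, pandas DataFrame).

    The DataFrame mirrors the stage-1 output CSV of the pipeline.
    """
    import pandas as pd

    results = []
    for i, s in enumerate(scaled):
        seed_i = None if seed is None else (seed + i) % (2**31)
        results.append(fit_state_space(s, method=method, starts=starts,
                                       seed=seed_i))
    rows = []
    for r in results:
        rows.append(dict(
            series_id=r.series_id, mu=r.params.mu, sigma2=r.params.sigma2,
            tau2=r.params.tau2, ci_lo=r.ci95_mu[0], ci_hi=r.ci95_mu[1],
            classification=r.classification, slope_lm=r.slope_lm,
            se_slope=r.se_slope, p_slope=r.p_slope, sd_raw=r.sd_raw,
            loglik=r.loglik, converged=r.converged,
        ))
    return results, pd.DataFrame(rows)
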