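"""First-stage event effects: spline fit of the relative mortality increase.

For each storm-location event the relative increase f(t) = Y/mu - 1 is
modelled over a window around the hit day t0 with a natural cubic spline
(6 knots per year by default) plus a level discontinuity at t0, estimated
by generalized least squares under the noise covariance fitted on control
days (Poisson part nu/mu on the diagonal, AR-correlated log-noise part
sigma^2 elsewhere). The period of concern (POC) is the first contiguous
post-t0 run of days whose 95% CI for f excludes 0; excess deaths, observed
and expected counts and the relative risk are accumulated over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from ._splines import natural_cubic_basis
from .baseline import BaselineFit, LocationSeries

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class EventEffect:
    """Estimated effect of one storm on one location's mortality."""

    event_id: str
    location: str
    cause: str
    t0: pd.Timestamp
    window: pd.DatetimeIndex
    f_hat: pd.Series
    se: pd.Series
    poc_start: pd.Timestamp | None = None
    poc_length: int = 0
    poc_longest_length: int = 0
    observed: float = np.nan
    expected: float = np.nan
    excess: float = np.nan
    excess_lo: float = np.nan
    excess_hi: float = np.nan
    rr: float = np.nan
    rr_lo: float = np.nan
    rr_hi: float = np.nan
    p_value: float = np.nan
    accumulation_days: pd.DatetimeIndex | None = None
    accumulation_fallback: bool = False
    rr_undefined: bool = False
    empty: bool = False
    coef: np.ndarray = field(default=None, repr=False)
    coef_cov: np.ndarray = field(default=None, repr=False)
    basis: np.ndarray = field(default=None, repr=False)

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"lo": self.f_hat - z * self.se, "hi": self.f_hat + z * self.se},
            index=self.f_hat.index,
        )


def event_basis(
    window: pd.DatetimeIndex,
    t0: pd.Timestamp,
    knots_per_year: int = 6,
) -> np.ndarray:
    """Design matrix for f(t): natural spline + post-t0 level jump.

    Interior knots are evenly spaced at a density of ``knots_per_year`` per
    365.25 days across the window; the jump column is the indicator of
    t >= t0 so f may be discontinuous on the hit day. Spline columns are
    centred on the pre-t0 segment (the jump column is already 0 there), so
    the basis is invariant under calendar shifts of the window.
    """
    window = pd.DatetimeIndex(window)
    t0 = pd.Timestamp(t0)
    if len(window) < 2:
        raise ValueError("window must span at least 2 days")
    if not (window[0] <= t0 <= window[-1]):
        raise ValueError("t0 must lie inside the window")
    t = (window - window[0]).days.to_numpy(dtype=float)
    span = t[-1] - t[0]
    n_interior = max(int(round(span * knots_per_year / 365.25)), 1)
    interior = np.linspace(t[0], t[-1], n_interior + 2)[1:-1]
    X = natural_cubic_basis(t, interior, (t[0], t[-1]))
    jump = np.asarray(window >= t0, dtype=float)
    pre = jump == 0.0
    if pre.any():
        X = X - X[pre].mean(axis=0)
    return np.column_stack([X, jump])


def _event_covariance(
    day_offsets: np.ndarray,
    mu: np.ndarray,
    nu: float,
    sigma: float,
    ar: tuple,
) -> np.ndarray:
    """Sigma_ij = delta_ij * nu/mu_i + sigma^2 * rho(|d_i - d_j|) (AR model)."""
    n = len(mu)
    lags = np.abs(day_offsets[:, None] - day_offsets[None, :]).astype(int)
    sigma2 = sigma**2
    if sigma2 > 0 and ar and any(a != 0 for a in ar):
        max_lag = lags.max()
        rho = np.zeros(max_lag + 1)
        rho[0] = 1.0
        p = len(ar)
        for l in range(1, max_lag + 1):
            rho[l] = sum(ar[k] * rho[abs(l - k - 1)] for k in range(p))
        cov = sigma2 * rho[lags]
    else:
        cov = np.zeros((n, n))
        np.fill_diagonal(cov, sigma2)
    cov = cov + np.diag(nu / mu)
    return cov


def fit_event_effect(
    series: LocationSeries,
    baseline: BaselineFit,
    t0: pd.Timestamp,
    window: pd.DatetimeIndex | None = None,
    other_events=(),
    exclusion_days: int = 60,
    event_id: str = "",
    knots_per_year: int = 6,
    window_half_days: int = 365,
    accumulation: str = "poc",
    poc_rule: str = "first",
    ci_level: float = 0.95,
) -> EventEffect:
    """GLS estimate of f(t), its SE, the POC and the event summaries.

    z_t = Y_t / mu_t - 1 over the window (days inside other events'
    [t0', t0' + exclusion_days] windows or exposure days are dropped from
    the fit) is regressed on :func:`event_basis` with covariance from the
    fitted noise structure. Predictions cover the full window. Excess
    deaths are sum(mu * f_hat) over the POC with SE through the same linear
    functional; observed = sum(Y), expected = observed - excess,
    RR = observed / expected with a delta-method CI on the log scale. If
    the POC is empty, summaries fall back to [t0, t0+2] and are flagged.
    """
    t0 = pd.Timestamp(t0)
    dates = series.dates
    if window is None:
        window = pd.date_range(
            t0 - pd.Timedelta(days=window_half_days),
            t0 + pd.Timedelta(days=window_half_days),
            freq="D",
        )
    window = pd.DatetimeIndex(window).intersection(dates)
    if len(window) < 2:
        raise ValueError("window has fewer than 2 days of data")

    dropped: set = set()
    for ev in other_events:
        o_t0 = pd.Timestamp(ev.t0)
        dropped.update(pd.Timestamp(d) for d in getattr(ev, "exposure_days", []))
        dropped.update(pd.date_range(o_t0, o_t0 + pd.Timedelta(days=exclusion_days), freq="D"))
    keep = ~window.isin(pd.DatetimeIndex(sorted(dropped))) if dropped else np.ones(len(window), bool)

    nu, sigma, ar = baseline.dispersion, baseline.noise_sd, baseline.ar_coefficients
    if np.isnan(nu):
        raise ValueError("noise structure not estimated; call estimate_noise first")

    X_full = event_basis(window, t0, knots_per_year=knots_per_year)
    eff = EventEffect(
        event_id=event_id,
        location=series.location,
        cause=baseline.cause,
        t0=t0,
        window=window,
        f_hat=pd.Series(np.nan, index=window),
        se=pd.Series(np.nan, index=window),
    )
    if keep.sum() <= X_full.shape[1]:
        warnings.warn(f"event {event_id}: all/most window days excluded; empty result")
        eff.empty = True
        return eff

    y = pd.Series(
        series.deaths(baseline.cause).astype(float), index=dates
    ).reindex(window).to_numpy()
    mu = baseline.mu.reindex(window).to_numpy()
    z = y / mu - 1.0
    day_off = (window - window[0]).days.to_numpy()

    Xf = X_full[keep]
    zf = z[keep]
    cov = _event_covariance(day_off[keep], mu[keep], nu, sigma, ar)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("noise covariance not positive definite; ridge repair applied")
        cov = cov + 1e-8 * np.trace(cov) / len(cov) * np.eye(len(cov))
        L = np.linalg.cholesky(cov)
    Xt = solve_triangular(L, Xf, lower=True)
    zt = solve_triangular(L, zf, lower=True)
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ zt)
    beta_cov = np.linalg.inv(XtX)

    f_hat = X_full @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X_full, beta_cov, X_full))
    eff.f_hat = pd.Series(f_hat, index=window)
    eff.se = pd.Series(se, index=window)
    eff.coef, eff.coef_cov, eff.basis = beta, beta_cov, X_full

    poc_start, poc_len, longest = detect_poc(eff, rule=poc_rule, ci_level=ci_level)
    eff.poc_start, eff.poc_length, eff.poc_longest_length = poc_start, poc_len, longest
    _summarize(eff, y, mu, accumulation=accumulation)
    return eff


def detect_poc(
    effect: EventEffect,
    rule: str = "first",
    ci_level: float = 0.95,
) -> tuple[pd.Timestamp | None, int, int]:
    """Period of concern: contiguous post-t0 run with CI lower bound > 0.

    Returns (start, length of the selected run, length of the longest
    run). ``rule='first'`` (default) selects the first run at/after t0;
    ``rule='longest'`` selects the longest.
    """
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    post = effect.window >= effect.t0
    lower = (effect.f_hat - z * effect.se).to_numpy()[post]
    days = effect.window[post]
    sig = lower > 0
    runs = []
    start = None
    for k, flag in enumerate(sig):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            runs.append((start, k - start))
            start = None
    if start is not None:
        runs.append((start, len(sig) - start))
    if not runs:
        return None, 0, 0
    longest = max(r[1] for r in runs)
    chosen = runs[0] if rule == "first" else max(runs, key=lambda r: r[1])
    return days[chosen[0]], chosen[1], longest


def _summarize(effect: EventEffect, y: np.ndarray, mu: np.ndarray, accumulation: str = "poc"):
    """Excess, observed, expected, RR over the accumulation window."""
    window = effect.window
    if effect.poc_length > 0 and accumulation == "poc":
        acc = pd.date_range(effect.poc_start, periods=effect.poc_length, freq="D")
        effect.accumulation_fallback = False
    else:
        acc = pd.date_range(effect.t0, effect.t0 + pd.Timedelta(days=2), freq="D")
        effect.accumulation_fallback = True
    acc = pd.DatetimeIndex(acc).intersection(window)
    effect.accumulation_days = acc
    in_acc = window.isin(acc)

    c = (mu[in_acc][:, None] * effect.basis[in_acc]).sum(axis=0)
    excess = float(c @ effect.coef)
    excess_se = float(np.sqrt(c @ effect.coef_cov @ c))
    observed = float(y[in_acc].sum())
    expected = observed - excess
    effect.observed = observed
    effect.excess = excess
    effect.excess_lo = excess - Z95 * excess_se
    effect.excess_hi = excess + Z95 * excess_se
    effect.expected = expected
    if expected <= 0:
        effect.rr_undefined = True
        warnings.warn(f"event {effect.event_id}: expected <= 0, RR undefined")
        return
    rr = observed / expected
    effect.rr = rr
    se_log_rr = excess_se / expected  # delta method
    if rr > 0:
        effect.rr_lo = float(np.exp(np.log(rr) - Z95 * se_log_rr))
        effect.rr_hi = float(np.exp(np.log(rr) + Z95 * se_log_rr))
        if se_log_rr > 0:
            effect.p_value = float(2.0 * stats.norm.sf(abs(np.log(rr)) / se_log_rr))
        else:
            effect.p_value = 1.0 if rr == 1.0 else 0.0


def summarize_event(effect: EventEffect) -> dict:
    """Event summary row (excess with CI, RR with CI, p)."""
    return {
        "event_id": effect.event_id,
        "location": effect.location,
        "cause": effect.cause,
        "t0": effect.t0.date(),
        "poc_start": effect.poc_start.date() if effect.poc_start is not None else None,
        "poc_length": effect.poc_length,
        "poc_longest_length": effect.poc_longest_length,
        "observed": effect.observed,
        "expected": effect.expected,
        "excess": effect.excess,
        "excess_lo": effect.excess_lo,
        "excess_hi": effect.excess_hi,
        "rr": effect.rr,
        "rr_lo": effect.rr_lo,
        "rr_hi": effect.rr_hi,
        "p": effect.p_value,
        "accumulation_fallback": effect.accumulation_fallback,
        "rr_undefined": effect.rr_undefined,
    }


def effects_to_frame(effects: list[EventEffect]) -> pd.DataFrame:
    return pd.DataFrame([summarize_event(e) for e in effects])
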