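"""Expected-mortality baseline: Poisson GLM on control days + noise structure.

The baseline models daily deaths as Poisson with log link on a design of
natural-spline trend, Fourier seasonality and day-of-week indicators, with
log annual population as offset, fitted on control (non-cyclone) days only.
The multiplicative noise is then characterised by a dispersion / log-noise
variance decomposition and an AR model of its autocorrelation, all from
control-day relative residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import CubicSpline

from ._splines import fourier_basis, natural_cubic_basis


@dataclass
class LocationSeries:
    """Daily mortality for one location plus annual population."""

    location: str
    country: str
    daily: pd.DataFrame  # columns: date, deaths_all[, deaths_cvd, deaths_resp][, rain_mm]
    population: pd.Series  # indexed by year

    def __post_init__(self):
        d = self.daily.copy()
        d["date"] = pd.to_datetime(d["date"])
        d = d.sort_values("date").reset_index(drop=True)
        dates = pd.DatetimeIndex(d["date"])
        if len(dates) > 1 and not (np.diff(dates.asi8) == 86400 * 10**9).all():
            gaps = dates[1:][np.diff(dates.asi8) != 86400 * 10**9]
            raise ValueError(f"dates not contiguous for {self.location}; first gap before {gaps[0].date()}")
        for col in d.columns:
            if col.startswith("deaths"):
                vals = d[col].to_numpy()
                if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                    raise ValueError(f"{col} must be non-negative integers")
        self.daily = d
        self.population = pd.Series(self.population).astype(float)
        covered = np.unique(dates.year)
        missing = [int(y) for y in covered if y not in self.population.index]
        if missing:
            raise ValueError(f"population missing for years {missing}")
        if (self.population <= 0).any():
            raise ValueError("population must be positive")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.daily["date"])

    def deaths(self, cause: str = "all") -> np.ndarray:
        return self.daily[f"deaths_{cause}"].to_numpy()

    def population_daily(self) -> np.ndarray:
        return self.population.reindex(self.dates.year).to_numpy()


def interpolate_population(decadal: dict[int, float] | pd.Series) -> pd.Series:
    """Natural cubic spline interpolation of decadal population to each year.

    Exact at the given years; a single point extrapolates as a constant
    (with a warning).
    """
    s = pd.Series(decadal).sort_index().astype(float)
    years = s.index.to_numpy(dtype=int)
    out_years = np.arange(years.min(), years.max() + 1)
    if len(s) == 1:
        warnings.warn("single population point: constant extrapolation")
        return pd.Series(s.iloc[0], index=out_years)
    cs = CubicSpline(years, s.to_numpy(), bc_type="natural")
    return pd.Series(cs(out_years), index=out_years)


def control_periods(
    series: LocationSeries,
    events,
    exclusion_days: int = 60,
) -> pd.DatetimeIndex:
    """Control days: all days minus exposure days minus [t0, t0 + exclusion_days].

    ``events`` is a list of exposure records (need ``t0`` and
    ``exposure_days`` attributes). Raises if no control days remain.
    """
    if exclusion_days < 1:
        raise ValueError("exclusion_days must be positive")
    excluded: set = set()
    for ev in events:
        excluded.update(pd.Timestamp(d) for d in ev.exposure_days)
        t0 = pd.Timestamp(ev.t0)
        excluded.update(pd.date_range(t0, t0 + pd.Timedelta(days=exclusion_days), freq="D"))
    control = series.dates.difference(pd.DatetimeIndex(sorted(excluded)))
    if len(control) == 0:
        raise ValueError("no control days remain; cannot fit baseline")
    return control


@dataclass
class BaselineFit:
    """Fitted expected-mortality model plus noise structure."""

    location: str
    cause: str
    params: pd.Series
    mu: pd.Series  # fitted expected deaths, every day
    design_info: dict
    glm_result: object = field(default=None, repr=False)
    dispersion: float = np.nan  # nu in Var(z) = nu/mu + sigma^2
    noise_sd: float = np.nan  # sigma_eps
    ar_coefficients: tuple = ()

    def __post_init__(self):
        if (self.mu <= 0).any():
            raise ValueError("fitted mu must be strictly positive")

    @property
    def noise(self) -> tuple[float, float, tuple]:
        return self.dispersion, self.noise_sd, self.ar_coefficients


def _baseline_design(
    dates: pd.DatetimeIndex,
    trend_knots_per_decade: float | None,
    harmonics: int,
    include_dow: bool = True,
) -> tuple[np.ndarray, dict]:
    t = (dates - dates[0]).days.to_numpy(dtype=float)
    lo, hi = t[0], t[-1]
    cols = [np.ones(len(t))]
    names = ["intercept"]
    interior = np.array([])
    if trend_knots_per_decade is not None and hi > lo:
        span_years = (hi - lo) / 365.25
        n_knots = max(int(round(span_years * trend_knots_per_decade / 10.0)), 0)
        interior = np.linspace(lo, hi, n_knots + 2)[1:-1] if n_knots else np.array([])
        trend = natural_cubic_basis(t, interior, (lo, hi))
        trend -= trend.mean(axis=0)
        cols.append(trend)
        names += [f"trend{k}" for k in range(trend.shape[1])]
    doy = (dates.dayofyear - 1).to_numpy(dtype=float)
    seas = fourier_basis(doy, harmonics)
    if seas.shape[1]:
        cols.append(seas)
        for h in range(1, harmonics + 1):
            names += [f"sin{h}", f"cos{h}"]
    if include_dow:
        dow = dates.dayofweek.to_numpy()
        cols.append(np.column_stack([(dow == d).astype(float) for d in range(1, 7)]))  # vs Monday
        names += [f"dow{d}" for d in range(1, 7)]
    X = np.column_stack(cols)
    info = {
        "trend_interior_knots": interior.tolist(),
        "trend_boundary": (float(lo), float(hi)),
        "harmonics": harmonics,
        "names": names,
        "origin": str(dates[0].date()),
    }
    return X, info


def fit_baseline(
    series: LocationSeries,
    control: pd.DatetimeIndex,
    cause: str = "all",
    trend_knots_per_decade: float | None = 10.0 / 7.0,
    harmonics: int = 2,
    include_dow: bool = True,
) -> BaselineFit:
    """Poisson GLM (log link) of deaths on trend/season/day-of-week, offset log N.

    Fitted on control days only; expected deaths predicted for every day.
    Defaults: one trend knot per 7 years, 2 seasonal harmonics.
    ``trend_knots_per_decade=None`` drops the trend, ``harmonics=0`` the
    seasonality and ``include_dow=False`` the day-of-week terms.
    """
    dates = series.dates
    X, info = _baseline_design(dates, trend_knots_per_decade, harmonics, include_dow)
    y = series.deaths(cause).astype(float)
    offset = np.log(series.population_daily())
    in_control = dates.isin(control)
    n_ctrl = int(in_control.sum())
    if n_ctrl < 10 * X.shape[1]:
        raise ValueError(
            f"only {n_ctrl} control days for {X.shape[1]} coefficients; need >= 10x"
        )
    model = sm.GLM(
        y[in_control],
        X[in_control],
        family=sm.families.Poisson(),
        offset=offset[in_control],
    )
    try:
        res = model.fit(maxiter=200, tol=1e-12)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"baseline GLM failed to converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"baseline GLM did not converge after {res.fit_history['iteration']} iterations")
    mu_all = np.exp(X @ res.params + offset)
    return BaselineFit(
        location=series.location,
        cause=cause,
        params=pd.Series(res.params, index=info["names"]),
        mu=pd.Series(mu_all, index=dates),
        design_info=info,
        glm_result=res,
    )


def estimate_noise(
    series: LocationSeries,
    baseline: BaselineFit,
    control: pd.DatetimeIndex,
    ar_order: int = 1,
) -> tuple[float, float, tuple]:
    """Moment estimation of (dispersion nu, noise SD sigma, AR coefficients).

    Relative residuals z = Y/mu - 1 on control days have variance
    nu/mu + sigma^2 and lagged covariances gamma_l = sigma^2 * rho_l (the
    Poisson part is white). For the default AR(1) noise rho_l = phi^l, so
    phi is estimated by pooling successive lag ratios,
    phi = sum_l gamma_l gamma_{l+1} / sum_l gamma_l^2, and sigma^2 by
    projecting (gamma_1..gamma_L) onto (phi..phi^L). nu follows from the
    variance decomposition. When the lag-1 covariance is not distinguishable
    from zero the noise is treated as white (phi = 0, sigma^2 = gamma_1+).

    Results are stored on ``baseline`` and returned.
    """
    dates = series.dates
    in_control = dates.isin(control)
    y = series.deaths(baseline.cause).astype(float)[in_control]
    mu = baseline.mu.to_numpy()[in_control]
    z = y / mu - 1.0
    n = len(z)
    if n < 3:
        raise ValueError("too few control days to estimate noise")

    if np.allclose(z, 0.0):
        baseline.dispersion, baseline.noise_sd, baseline.ar_coefficients = 1.0, 0.0, (0.0,) * ar_order
        return baseline.noise

    # lagged covariances restricted to control-day pairs at exact calendar lag
    ctrl_dates = dates[in_control]
    pos = pd.Series(np.arange(n), index=ctrl_dates)
    n_lags = max(6, ar_order + 1)
    gamma = np.zeros(n_lags + 1)
    gamma[0] = float(np.mean(z * z))
    for lag in range(1, n_lags + 1):
        partner = ctrl_dates + pd.Timedelta(days=lag)
        mask = partner.isin(ctrl_dates)
        if mask.sum() < 10:
            continue
        i1 = pos[ctrl_dates[mask]].to_numpy()
        i2 = pos[partner[mask]].to_numpy()
        gamma[lag] = float(np.mean(z[i1] * z[i2]))

    gamma1_se = gamma[0] / np.sqrt(n)
    if gamma[1] <= 2.0 * gamma1_se:
        # no detectable serial correlation: white noise component
        phi = 0.0
        sigma2 = max(float(gamma[1]), 0.0)
        if gamma[1] < 0:
            warnings.warn("negative noise variance estimate clamped to 0 (pure Poisson)")
    else:
        num = float(np.sum(gamma[1:n_lags] * gamma[2 : n_lags + 1]))
        den = float(np.sum(gamma[1:n_lags] ** 2))
        phi = float(np.clip(num / den, 0.0, 0.99)) if den > 0 else 0.0
        if phi > 0.05:
            w = phi ** np.arange(1, n_lags + 1)
            sigma2 = max(float(gamma[1:] @ w / (w @ w)), 0.0)
        else:
            sigma2 = max(float(gamma[1]), 0.0)
    sigma = float(np.sqrt(sigma2))

    inv_mu_mean = float(np.mean(1.0 / mu))
    nu = (gamma[0] - sigma2) / inv_mu_mean
    if nu <= 0:
        warnings.warn("non-positive dispersion estimate; falling back to nu = 1")
        nu = 1.0
    nu = float(nu)

    if sigma2 <= 1e-12:
        ar = (0.0,) * ar_order
    elif ar_order == 1:
        ar = (phi,)
    else:
        rho = np.clip(gamma[1 : ar_order + 1] / sigma2, -0.99, 0.99)
        rho_full = np.concatenate([[1.0], rho])
        R = np.empty((ar_order, ar_order))
        for i in range(ar_order):
            for j in range(ar_order):
                R[i, j] = rho_full[abs(i - j)]
        ar = tuple(float(a) for a in np.linalg.solve(R, rho))
    baseline.dispersion, baseline.noise_sd, baseline.ar_coefficients = nu, sigma, ar
    return baseline.noise


def baseline_to_dict(fit: BaselineFit) -> dict:
    return {
        "location": fit.location,
        "cause": fit.cause,
        "params": {k: float(v) for k, v in fit.params.items()},
        "design_info": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in fit.design_info.items()
        },
        "dispersion": None if np.isnan(fit.dispersion) else float(fit.dispersion),
        "noise_sd": None if np.isnan(fit.noise_sd) else float(fit.noise_sd),
        "ar_coefficients": [float(a) for a in fit.ar_coefficients],
    }
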