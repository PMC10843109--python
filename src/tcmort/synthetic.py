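"""Synthetic storms, populations, rainfall and mortality with known truth.

The mortality generator draws daily counts from the mixed Poisson model
used downstream: Y_t | eps_t ~ Poisson(mu_t * (1 + f(t)) * eps_t), with
mu_t composed of a population offset, slow log-linear trend, yearly
seasonality and day-of-week effects, and eps_t a log-normal AR(1)
multiplicative noise normalised so E[eps] = 1. Injected event effects f(t)
of known shape/amplitude/duration are recorded in truth records so that
every downstream estimator can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .windfield import GridSpec, TCTrack, holland_b_param, AIR_DENSITY

EFFECT_SHAPES = ("rect", "triangular", "exp-decay")


@dataclass
class InjectedEffect:
    """One TC-like event effect injected into a location's mortality."""

    location: str
    t0: pd.Timestamp
    shape: str = "rect"
    peak_pct: float = 30.0  # percent increase at peak
    duration_days: int = 21

    def __post_init__(self):
        self.t0 = pd.Timestamp(self.t0)
        if self.shape not in EFFECT_SHAPES:
            raise ValueError(f"shape must be one of {EFFECT_SHAPES}")
        if self.duration_days < 1:
            raise ValueError("duration must be >= 1 day")
        if self.peak_pct <= -100:
            raise ValueError("peak percent increase must exceed -100")

    def f_values(self) -> np.ndarray:
        """Relative increase f on each of the duration days (unitless)."""
        k = np.arange(self.duration_days, dtype=float)
        peak = self.peak_pct / 100.0
        if self.shape == "rect":
            return np.full(self.duration_days, peak)
        if self.shape == "triangular":
            return peak * (1.0 - k / self.duration_days)
        return peak * np.exp(-3.0 * k / self.duration_days)


@dataclass
class SimulationConfig:
    n_locations: int = 1
    start_year: int = 2000
    years: int = 10
    baseline_rate: float = 10.0  # expected deaths/day at reference population
    trend_per_decade: float = 0.0  # log-scale slope per decade
    seasonal_amplitude: float = 0.0  # log scale
    dow_effects: tuple = (0.0,) * 7  # log scale, Monday..Sunday
    noise_sd: float = 0.0  # marginal SD of log-noise
    noise_ar1: float = 0.0  # lag-1 autocorrelation of log-noise
    injected_effects: list = field(default_factory=list)
    base_population: float = 1e5
    pop_growth_per_year: float = 0.0  # relative
    cvd_fraction: float = 0.35
    resp_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_locations < 1 or self.years < 1:
            raise ValueError("need at least 1 location and 1 year")
        if abs(self.noise_ar1) >= 1:
            raise ValueError("|noise_ar1| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries")
        self.injected_effects = [
            e if isinstance(e, InjectedEffect) else InjectedEffect(**e)
            for e in self.injected_effects
        ]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(
            f"{self.start_year}-01-01", f"{self.start_year + self.years - 1}-12-31", freq="D"
        )


@dataclass
class TruthRecord:
    """Ground truth for one injected effect (recovery-test oracle)."""

    location: str
    t0: pd.Timestamp
    shape: str
    f_series: pd.Series  # true f(t) over the effect window
    poc_days: pd.DatetimeIndex  # days with true f > 0
    true_expected: float  # sum of mu over the effect window
    true_excess: float  # sum of mu * f over the effect window


def gen_tracks(
    n_storms: int,
    region: tuple[float, float, float, float],
    seed: int,
    start_year: int = 2000,
    years: int = 10,
    vmax_bounds_kn: tuple[float, float] = (20.0, 120.0),
) -> list[TCTrack]:
    """Random 6-hourly storm tracks crossing ``region`` (lat0, lat1, lon0, lon1).

    Smooth random-walk motion, an intensify-peak-decay pressure-deficit
    lifecycle, constant radius of maximum winds in [20, 80] km, and max wind
    tied to the pressure deficit through the gradient-wind peak value,
    clipped to ``vmax_bounds_kn``. Deterministic given the seed.
    """
    if n_storms < 1:
        raise ValueError("n_storms must be >= 1")
    lat0, lat1, lon0, lon1 = region
    if not (lat0 < lat1 and lon0 < lon1):
        raise ValueError("invalid region box: need lat0 < lat1 and lon0 < lon1")
    rng = np.random.default_rng(seed)
    tracks = []
    for k in range(n_storms):
        n_pts = int(rng.integers(12, 29))  # 3-7 days at 6-hourly
        # start just outside/inside one lon edge, random lat in box
        lat = rng.uniform(lat0, lat1)
        lon = lon1 + rng.uniform(0.0, 1.0)
        heading = np.pi + rng.normal(0.0, 0.3)  # roughly westward
        speed_deg = rng.uniform(0.4, 0.9)  # degrees per 6 h
        lats, lons = [lat], [lon]
        for _ in range(n_pts - 1):
            heading += rng.normal(0.0, 0.15)
            lat += speed_deg * np.sin(heading) * 0.5
            lon += speed_deg * np.cos(heading)
            lats.append(lat)
            lons.append(lon)
        dp_max = rng.uniform(20.0, 60.0)  # hPa
        phase = np.linspace(0.0, np.pi, n_pts)
        dp = dp_max * np.sin(phase) ** 0.8
        dp = np.maximum(dp, 1.0)
        env = np.full(n_pts, 1010.0)
        rmw = np.full(n_pts, rng.uniform(20.0, 80.0))
        b = holland_b_param(dp, 0.0, np.abs(np.asarray(lats)), 5.0)
        vmax_ms = np.sqrt(b * dp * 100.0 / (AIR_DENSITY * np.e))
        vmax_kn = np.clip(vmax_ms / 0.514444, *vmax_bounds_kn)
        day0 = pd.Timestamp(f"{start_year}-01-01") + pd.Timedelta(
            days=int(rng.integers(0, years * 365 - 10))
        )
        times = day0 + pd.to_timedelta(np.arange(n_pts) * 6, unit="h")
        tracks.append(
            TCTrack(
                event_id=f"SYN{k:03d}",
                times=times,
                lat=np.asarray(lats),
                lon=np.asarray(lons),
                central_pressure=env - dp,
                env_pressure=env,
                rmw_km=rmw,
                vmax_kn=vmax_kn,
            )
        )
    return tracks


def gen_population(
    grid: GridSpec,
    decades: list[int],
    seed: int,
    growth_per_decade: float = 1.05,
    base_mean: float = 5e4,
) -> pd.DataFrame:
    """Decadal gridded population: smooth positive field with exact decadal growth.

    Returns long format (cell_lat, cell_lon, year, population).
    """
    if len(decades) < 2:
        raise ValueError("need at least 2 decades")
    rng = np.random.default_rng(seed)
    shape = grid.shape
    field_log = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=2.0)
    base = base_mean * np.exp(field_log - field_log.mean())
    lats = grid.lat_centers
    lons = grid.lon_centers
    frames = []
    for k, year in enumerate(sorted(decades)):
        pop = base * growth_per_decade**k
        lat_mesh, lon_mesh = np.meshgrid(lats, lons, indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "cell_lat": lat_mesh.ravel(),
                    "cell_lon": lon_mesh.ravel(),
                    "year": year,
                    "population": pop.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _ar1_lognormal_noise(rng, n: int, sd: float, phi: float) -> np.ndarray:
    """Multiplicative noise eps with E[eps] = 1; log eps is stationary AR(1)."""
    if sd == 0.0:
        return np.ones(n)
    eta = np.empty(n)
    eta[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        eta[t] = phi * eta[t - 1] + shocks[t - 1]
    return np.exp(eta - sd**2 / 2.0)


@dataclass
class SimulatedData:
    daily: pd.DataFrame  # location, date, deaths_all, deaths_cvd, deaths_resp, rain_mm
    population: pd.DataFrame  # location, year, population
    truth: list  # TruthRecord per injected effect
    mu: pd.DataFrame  # location, date, mu (true expected deaths)


def gen_location_series(
    cfg: SimulationConfig,
    storm_days: dict[str, list] | None = None,
) -> SimulatedData:
    """Simulate daily mortality + rainfall per location under the mixed Poisson model.

    ``storm_days`` optionally maps location -> list of dates whose rainfall
    is inflated (storm bursts); injected effect days are always inflated.
    """
    dates = cfg.dates
    rng = np.random.default_rng(cfg.seed)
    for eff in cfg.injected_effects:
        end = eff.t0 + pd.Timedelta(days=eff.duration_days - 1)
        if eff.t0 < dates[0] or end > dates[-1]:
            raise ValueError(f"injected effect at {eff.t0.date()} outside simulated span")

    n = len(dates)
    t_years = (dates - dates[0]).days.to_numpy() / 365.25
    doy = dates.dayofyear.to_numpy()
    dow = dates.dayofweek.to_numpy()
    years = dates.year.to_numpy()

    loc_ids = [f"loc{j:03d}" for j in range(cfg.n_locations)]
    daily_frames, mu_frames, pop_frames, truths = [], [], [], []
    for loc in loc_ids:
        pop_by_year = {
            int(y): cfg.base_population * (1.0 + cfg.pop_growth_per_year) ** (y - cfg.start_year)
            for y in np.unique(years)
        }
        pop_daily = np.array([pop_by_year[int(y)] for y in years])
        log_mu = (
            np.log(cfg.baseline_rate)
            + np.log(pop_daily / cfg.base_population)  # offset
            + cfg.trend_per_decade * t_years / 10.0
            + cfg.seasonal_amplitude * np.cos(2.0 * np.pi * (doy - 15) / 365.25)
            + np.array([cfg.dow_effects[d] for d in dow])
        )
        mu = np.exp(log_mu)

        f = np.zeros(n)
        loc_effects = [e for e in cfg.injected_effects if e.location == loc]
        for eff in loc_effects:
            idx0 = int((eff.t0 - dates[0]).days)
            vals = eff.f_values()
            f[idx0 : idx0 + eff.duration_days] += vals
            window = dates[idx0 : idx0 + eff.duration_days]
            truths.append(
                TruthRecord(
                    location=loc,
                    t0=eff.t0,
                    shape=eff.shape,
                    f_series=pd.Series(vals, index=window),
                    poc_days=window[vals > 0],
                    true_expected=float(mu[idx0 : idx0 + eff.duration_days].sum()),
                    true_excess=float((mu[idx0 : idx0 + eff.duration_days] * vals).sum()),
                )
            )

        eps = _ar1_lognormal_noise(rng, n, cfg.noise_sd, cfg.noise_ar1)
        lam = mu * (1.0 + f) * eps
        deaths = rng.poisson(lam)
        deaths_cvd = rng.binomial(deaths, cfg.cvd_fraction)
        deaths_resp = rng.binomial(deaths, cfg.resp_fraction)

        # seasonal gamma rainfall with storm-day bursts
        rain_scale = 4.0 * (1.0 + 0.5 * np.sin(2.0 * np.pi * doy / 365.25))
        rain = rng.gamma(shape=0.7, scale=rain_scale)
        burst_days = set()
        for eff in loc_effects:
            for d in pd.date_range(eff.t0, periods=eff.duration_days):
                burst_days.add(d)
        if storm_days and loc in storm_days:
            burst_days.update(pd.Timestamp(d) for d in storm_days[loc])
        if burst_days:
            mask = dates.isin(sorted(burst_days))
            rain[mask] += rng.gamma(shape=2.0, scale=30.0, size=int(mask.sum()))

        daily_frames.append(
            pd.DataFrame(
                {
                    "location": loc,
                    "date": dates,
                    "deaths_all": deaths,
                    "deaths_cvd": deaths_cvd,
                    "deaths_resp": deaths_resp,
                    "rain_mm": rain,
                }
            )
        )
        mu_frames.append(pd.DataFrame({"location": loc, "date": dates, "mu": mu}))
        pop_frames.append(
            pd.DataFrame(
                {
                    "location": loc,
                    "year": sorted(pop_by_year),
                    "population": [pop_by_year[y] for y in sorted(pop_by_year)],
                }
            )
        )

    return SimulatedData(
        daily=pd.concat(daily_frames, ignore_index=True),
        population=pd.concat(pop_frames, ignore_index=True),
        truth=truths,
        mu=pd.concat(mu_frames, ignore_index=True),
    )
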