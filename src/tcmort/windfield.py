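"""Parametric cyclone wind fields and gridded exposure classification.

Converts best-track storm records into daily maximum sustained winds on a
regular lat/lon grid (default 0.5 deg) via the Holland gradient-wind
profile, then derives per-location exposure records: exposure days (wind at
or above a gale-force threshold), the hit day t0, the event maximum wind
and cumulative rainfall around t0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Unit conversion factors (international definitions).
KNOT_TO_MS = 0.514444
KNOT_TO_KMH = 1.852
KNOT_TO_MPH = 1.15078

AIR_DENSITY = 1.15  # kg/m^3, standard near-surface value for gradient wind
OMEGA_EARTH = 7.2921e-5  # rad/s
EARTH_RADIUS_KM = 6371.0


def _require_nonnegative(v, name: str):
    if np.any(np.asarray(v) < 0):
        raise ValueError(f"{name} must be non-negative")


def knots_to_ms(v):
    """Knots -> metres per second."""
    _require_nonnegative(v, "wind speed")
    return np.multiply(v, KNOT_TO_MS)


def ms_to_knots(v):
    """Metres per second -> knots."""
    _require_nonnegative(v, "wind speed")
    return np.divide(v, KNOT_TO_MS)


def knots_to_kmh(v):
    """Knots -> kilometres per hour."""
    _require_nonnegative(v, "wind speed")
    return np.multiply(v, KNOT_TO_KMH)


def knots_to_mph(v):
    """Knots -> miles per hour."""
    _require_nonnegative(v, "wind speed")
    return np.multiply(v, KNOT_TO_MPH)


@dataclass
class TCTrack:
    """One storm's best-track sequence.

    Attributes
    ----------
    event_id : storm identifier.
    times : UTC timestamps, strictly increasing.
    lat, lon : centre position in degrees.
    central_pressure, env_pressure : hPa; environmental >= central.
    rmw_km : radius of maximum winds.
    vmax_kn : maximum sustained wind, knots.
    """

    event_id: str
    times: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    central_pressure: np.ndarray
    env_pressure: np.ndarray
    rmw_km: np.ndarray
    vmax_kn: np.ndarray

    def __post_init__(self):
        self.times = pd.DatetimeIndex(self.times)
        for name in ("lat", "lon", "central_pressure", "env_pressure", "rmw_km", "vmax_kn"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        for name in ("lat", "lon", "central_pressure", "env_pressure", "rmw_km", "vmax_kn"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"track field {name} length mismatch")
        if n >= 2 and not (np.diff(self.times.asi8) > 0).all():
            raise ValueError(f"track {self.event_id}: times must be strictly increasing")
        if np.any(self.env_pressure < self.central_pressure):
            raise ValueError(f"track {self.event_id}: environmental pressure below central")
        if np.any(np.abs(self.lat) > 90):
            raise ValueError(f"track {self.event_id}: latitude outside [-90, 90]")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SID": self.event_id,
                "ISO_TIME": self.times,
                "LAT": self.lat,
                "LON": self.lon,
                "PRES": self.central_pressure,
                "ENV_PRES": self.env_pressure,
                "RMW": self.rmw_km,
                "WIND": self.vmax_kn,
            }
        )


def read_tracks_csv(path) -> list[TCTrack]:
    """Read IBTrACS-like CSV (SID, ISO_TIME, LAT, LON, PRES, ENV_PRES, RMW, WIND)."""
    df = pd.read_csv(path, parse_dates=["ISO_TIME"])
    tracks = []
    for sid, g in df.groupby("SID", sort=True):
        g = g.sort_values("ISO_TIME")
        tracks.append(
            TCTrack(
                event_id=str(sid),
                times=g["ISO_TIME"].to_numpy(),
                lat=g["LAT"].to_numpy(),
                lon=g["LON"].to_numpy(),
                central_pressure=g["PRES"].to_numpy(),
                env_pressure=g["ENV_PRES"].to_numpy(),
                rmw_km=g["RMW"].to_numpy(),
                vmax_kn=g["WIND"].to_numpy(),
            )
        )
    return tracks


def write_tracks_csv(tracks: list[TCTrack], path) -> None:
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid defined by its bounding box and resolution.

    Cells are indexed 0-based from the south-west corner; coordinates
    reported are cell centres.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.5

    def __post_init__(self):
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("degenerate grid box")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def lat_centers(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.resolution))
        return self.lat_min + self.resolution * (np.arange(n) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.resolution))
        return self.lon_min + self.resolution * (np.arange(n) + 0.5)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lat_centers), len(self.lon_centers))

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """0-based (row, col) of the cell containing a point; raises if outside."""
        if not (self.lat_min <= lat <= self.lat_max and self.lon_min <= lon <= self.lon_max):
            raise ValueError(f"point ({lat}, {lon}) outside grid box")
        i = min(int((lat - self.lat_min) / self.resolution), self.shape[0] - 1)
        j = min(int((lon - self.lon_min) / self.resolution), self.shape[1] - 1)
        return i, j


@dataclass
class WindGrid:
    """Per-storm daily maximum sustained wind (m/s) on a grid."""

    event_id: str
    grid: GridSpec
    dates: pd.DatetimeIndex
    wind_ms: np.ndarray  # (n_days, n_lat, n_lon)

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.wind_ms = np.asarray(self.wind_ms, dtype=float)
        if self.wind_ms.shape != (len(self.dates),) + self.grid.shape:
            raise ValueError("wind array shape does not match grid/dates")
        if np.any(self.wind_ms < 0):
            raise ValueError("negative wind speeds")

    def cell_series(self, i: int, j: int) -> pd.Series:
        return pd.Series(self.wind_ms[:, i, j], index=self.dates)

    def to_frame(self) -> pd.DataFrame:
        """Long format: event, date, cell_lat, cell_lon, wind_ms (nonzero cells)."""
        lats = self.grid.lat_centers
        lons = self.grid.lon_centers
        rows = []
        for d_idx, date in enumerate(self.dates):
            ii, jj = np.nonzero(self.wind_ms[d_idx])
            for i, j in zip(ii, jj):
                rows.append((self.event_id, date.date(), lats[i], lons[j], self.wind_ms[d_idx, i, j]))
        return pd.DataFrame(rows, columns=["event", "date", "cell_lat", "cell_lon", "wind_ms"])


def coriolis(lat_deg) -> np.ndarray:
    return 2.0 * OMEGA_EARTH * np.sin(np.deg2rad(lat_deg))


def holland_b_param(delta_p_hpa, dp_dt_hpa_per_h=0.0, lat_deg=20.0, v_trans_ms=0.0):
    """Holland shape parameter B from storm state (surface regression form).

    B = -4.4e-5 dp^2 + 0.01 dp + 0.03 dp/dt - 0.014 |lat| + 0.15 vt^x + 1,
    x = 0.6 (1 - dp/215); dp in hPa, dp/dt in hPa/h, vt in m/s. Clipped to
    [0.5, 2.5].
    """
    dp = np.maximum(np.asarray(delta_p_hpa, dtype=float), 0.0)
    x = 0.6 * (1.0 - dp / 215.0)
    b = (
        -4.4e-5 * dp**2
        + 0.01 * dp
        + 0.03 * np.asarray(dp_dt_hpa_per_h, dtype=float)
        - 0.014 * np.abs(lat_deg)
        + 0.15 * np.asarray(v_trans_ms, dtype=float) ** x
        + 1.0
    )
    return np.clip(b, 0.5, 2.5)


def holland_wind_speed(
    r_km,
    delta_p_pa: float,
    r_max_km: float,
    b: float,
    lat_deg: float,
    translation_ms: float | None = None,
    surface_reduction: float = 1.0,
    translation_fraction: float = 1.0,
):
    """Sustained wind (m/s) at radius ``r_km`` from the storm centre.

    Gradient wind
        V(r) = sqrt( B dp / rho * (rm/r)^B exp(-(rm/r)^B) + (r fc / 2)^2 )
               - r fc / 2
    with rho = 1.15 kg/m^3 and Coriolis fc from latitude. When a
    translation speed is given, an asymmetry term bounded by half the
    translation speed is added: fraction * vt * rm*r / (rm^2 + r^2). The
    result is scaled by ``surface_reduction``. r = 0 returns 0 (vortex
    centre).
    """
    if delta_p_pa < 0:
        raise ValueError("pressure deficit must be non-negative")
    if not (0.5 <= b <= 2.5):
        raise ValueError(f"Holland B parameter {b} outside [0.5, 2.5]")
    if r_max_km <= 0:
        raise ValueError("radius of maximum winds must be positive")
    r_km = np.asarray(r_km, dtype=float)
    _require_nonnegative(r_km, "radius")
    scalar = r_km.ndim == 0
    r_km = np.atleast_1d(r_km)

    v = np.zeros_like(r_km)
    pos = r_km > 0
    r_m = r_km[pos] * 1000.0
    fc = abs(coriolis(lat_deg))
    ratio_b = (r_max_km / r_km[pos]) ** b
    core = b * delta_p_pa / AIR_DENSITY * ratio_b * np.exp(-ratio_b)
    cor_term = r_m * fc / 2.0
    v[pos] = np.sqrt(core + cor_term**2) - cor_term
    if translation_ms is not None and translation_ms > 0:
        rm, rr = r_max_km, r_km[pos]
        atten = rm * rr / (rm**2 + rr**2)  # bounded by 1/2, peaks at r = rm
        v[pos] = v[pos] + translation_fraction * translation_ms * atten
    v = np.maximum(v, 0.0) * surface_reduction
    return float(v[0]) if scalar else v


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine distance in km; broadcasts over array inputs."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _interpolate_track(track: TCTrack, step_minutes: int):
    """Linear interpolation of the track in time; returns snapshot arrays."""
    t0 = track.times.asi8[0]
    t_end = track.times.asi8[-1]
    step_ns = int(step_minutes * 60 * 1e9)
    snap_ns = np.arange(t0, t_end + 1, step_ns)
    t_rel = (track.times.asi8 - t0).astype(float)
    s_rel = (snap_ns - t0).astype(float)
    lat = np.interp(s_rel, t_rel, track.lat)
    lon = np.interp(s_rel, t_rel, track.lon)
    pres = np.interp(s_rel, t_rel, track.central_pressure)
    env = np.interp(s_rel, t_rel, track.env_pressure)
    rmw = np.interp(s_rel, t_rel, track.rmw_km)
    times = pd.DatetimeIndex(snap_ns.astype("datetime64[ns]"))
    # translation speed (m/s) by centred finite differences of position
    if len(times) > 1:
        dt_s = step_minutes * 60.0
        dist = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) * 1000.0
        seg = dist / dt_s
        v_trans = np.empty(len(times))
        v_trans[0], v_trans[-1] = seg[0], seg[-1]
        v_trans[1:-1] = 0.5 * (seg[:-1] + seg[1:])
        dpdt = np.gradient(pres, dt_s / 3600.0)  # hPa per hour
    else:
        v_trans = np.zeros(1)
        dpdt = np.zeros(1)
    return times, lat, lon, pres, env, rmw, v_trans, dpdt


def rasterize_storm(
    track: TCTrack,
    grid: GridSpec,
    interp_step_minutes: int = 60,
    cutoff_km: float = 500.0,
    surface_reduction: float = 0.9,
    b_param: float | None = None,
    with_translation: bool = True,
) -> WindGrid:
    """Daily maximum sustained wind per grid cell for one storm.

    The track is linearly interpolated in time; at each snapshot the
    Holland profile is evaluated at every cell centroid's great-circle
    distance to the centre; the daily field is the max over the UTC day's
    snapshots. Cells beyond ``cutoff_km`` are 0.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 points to rasterize")
    times, lat, lon, pres, env, rmw, v_trans, dpdt = _interpolate_track(track, interp_step_minutes)
    lat_c = grid.lat_centers
    lon_c = grid.lon_centers
    lat_mesh, lon_mesh = np.meshgrid(lat_c, lon_c, indexing="ij")

    days = times.floor("D")
    unique_days = days.unique()
    out = np.zeros((len(unique_days), len(lat_c), len(lon_c)))
    day_pos = {d: k for k, d in enumerate(unique_days)}
    for s in range(len(times)):
        dp_hpa = max(env[s] - pres[s], 0.0)
        if dp_hpa <= 0:
            continue
        b = b_param if b_param is not None else float(
            holland_b_param(dp_hpa, dpdt[s], lat[s], v_trans[s])
        )
        r = great_circle_km(lat[s], lon[s], lat_mesh, lon_mesh)
        v = holland_wind_speed(
            r.ravel(),
            dp_hpa * 100.0,
            rmw[s],
            b,
            lat[s],
            translation_ms=v_trans[s] if with_translation else None,
            surface_reduction=surface_reduction,
        ).reshape(r.shape)
        v[r > cutoff_km] = 0.0
        k = day_pos[days[s]]
        np.maximum(out[k], v, out=out[k])
    return WindGrid(event_id=track.event_id, grid=grid, dates=unique_days, wind_ms=out)


@dataclass
class ExposureRecord:
    """One storm-location exposure: hit day, exposure days, wind, rain."""

    location: str
    event_id: str
    t0: pd.Timestamp
    exposure_days: list = field(default_factory=list)
    event_max_wind_kn: float = np.nan
    cumulative_rain_mm: float = np.nan
    rain_missing: bool = False
    rain_window_days: int = 2

    def __post_init__(self):
        self.t0 = pd.Timestamp(self.t0)
        self.exposure_days = sorted(pd.Timestamp(d) for d in self.exposure_days)
        if self.exposure_days and self.t0 != self.exposure_days[0]:
            raise ValueError("t0 must equal the earliest exposure day")

    @property
    def year(self) -> int:
        return int(self.t0.year)


def classify_exposure(
    wind: WindGrid,
    locations: dict[str, tuple[float, float]],
    rain: pd.DataFrame | None = None,
    rain_window_days: int = 2,
    threshold_kn: float = 34.0,
    wind_conversion: float = 1.0,
) -> list[ExposureRecord]:
    """Per-location exposure records for one storm's wind grid.

    ``locations`` maps location id -> (lat, lon) centroid; each centroid
    must fall in one grid cell. ``rain`` is long format (location, date,
    rain_mm). Exposure days are days with cell wind (converted to knots and
    multiplied by ``wind_conversion``) at or above ``threshold_kn``
    (inclusive). Cumulative rain is summed over [t0 - rain_window, t0];
    missing rain days flag the record instead of failing.
    """
    records: list[ExposureRecord] = []
    rain_lookup: dict[str, pd.Series] = {}
    if rain is not None and len(rain):
        r = rain.copy()
        r["date"] = pd.to_datetime(r["date"])
        for loc, g in r.groupby("location"):
            rain_lookup[str(loc)] = g.set_index("date")["rain_mm"]

    for loc, (lat, lon) in locations.items():
        i, j = wind.grid.cell_of(lat, lon)
        series_kn = ms_to_knots(wind.cell_series(i, j).to_numpy()) * wind_conversion
        # inclusive threshold; tolerance guards the knot<->m/s round trip
        exposed = wind.dates[series_kn >= threshold_kn * (1.0 - 1e-12)]
        if len(exposed) == 0:
            continue
        t0 = exposed.min()
        max_wind = float(series_kn[series_kn >= threshold_kn * (1.0 - 1e-12)].max())
        rain_sum = np.nan
        missing = True
        if str(loc) in rain_lookup:
            window = pd.date_range(t0 - pd.Timedelta(days=rain_window_days), t0, freq="D")
            rs = rain_lookup[str(loc)].reindex(window)
            if rs.notna().all():
                rain_sum = float(rs.sum())
                missing = False
        records.append(
            ExposureRecord(
                location=str(loc),
                event_id=wind.event_id,
                t0=t0,
                exposure_days=list(exposed),
                event_max_wind_kn=max_wind,
                cumulative_rain_mm=rain_sum,
                rain_missing=missing,
                rain_window_days=rain_window_days,
            )
        )
        if missing and rain is not None:
            warnings.warn(f"rainfall missing around t0 for location {loc}, storm {wind.event_id}")
    return records


def exposures_to_frame(records: list[ExposureRecord]) -> pd.DataFrame:
    rows = [
        {
            "location": r.location,
            "event_id": r.event_id,
            "t0": r.t0.date(),
            "n_exposure_days": len(r.exposure_days),
            "event_max_wind_kn": r.event_max_wind_kn,
            "cumulative_rain_mm": r.cumulative_rain_mm,
            "rain_missing": r.rain_missing,
            "rain_window_days": r.rain_window_days,
            "year": r.year,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "location",
            "event_id",
            "t0",
            "n_exposure_days",
            "event_max_wind_kn",
            "cumulative_rain_mm",
            "rain_missing",
            "rain_window_days",
            "year",
        ],
    )
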