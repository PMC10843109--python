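import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcmort.baseline import (
    BaselineFit,
    LocationSeries,
    control_periods,
    estimate_noise,
    fit_baseline,
    interpolate_population,
)
from tcmort.windfield import ExposureRecord
from tests.conftest import simulate_one_location


def natural_spline_oracle(xk, yk, x):
    """Brute-force natural cubic spline: solve the tridiagonal M-system."""
    xk = np.asarray(xk, float)
    yk = np.asarray(yk, float)
    n = len(xk)
    h = np.diff(xk)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0  # natural: zero second derivative at the ends
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1] / 6.0
        A[i, i] = (h[i - 1] + h[i]) / 3.0
        A[i, i + 1] = h[i] / 6.0
        b[i] = (yk[i + 1] - yk[i]) / h[i] - (yk[i] - yk[i - 1]) / h[i - 1]
    M = np.linalg.solve(A, b)
    out = np.empty(len(np.atleast_1d(x)), float)
    for k, xv in enumerate(np.atleast_1d(x)):
        i = np.clip(np.searchsorted(xk, xv) - 1, 0, n - 2)
        hi = h[i]
        out[k] = (
            M[i] * (xk[i + 1] - xv) ** 3 / (6 * hi)
            + M[i + 1] * (xv - xk[i]) ** 3 / (6 * hi)
            + (yk[i] / hi - M[i] * hi / 6) * (xk[i + 1] - xv)
            + (yk[i + 1] / hi - M[i + 1] * hi / 6) * (xv - xk[i])
        )
    return out


class TestInterpolatePopulation:
    def test_constant_data(self):
        out = interpolate_population({1990: 100.0, 2000: 100.0})
        assert (out == 100.0).all()
        assert list(out.index) == list(range(1990, 2001))

    def test_linear_reproduction(self):
        out = interpolate_population({1990: 100.0, 2000: 110.0, 2010: 120.0})
        assert out[1995] == pytest.approx(105.0, abs=1e-9)
        assert out[2005] == pytest.approx(115.0, abs=1e-9)

    def test_exact_at_knots(self):
        vals = {1990: 100.0, 2000: 130.0, 2010: 120.0, 2020: 150.0}
        out = interpolate_population(vals)
        for y, v in vals.items():
            assert out[y] == pytest.approx(v, abs=1e-9)

    def test_against_tridiagonal_oracle(self):
        years = np.array([1990, 2000, 2010, 2020])
        vals = np.array([100.0, 130.0, 120.0, 150.0])
        out = interpolate_population(dict(zip(years, vals)))
        mids = np.array([1995, 2005, 2015])
        expect = natural_spline_oracle(years, vals, mids)
        np.testing.assert_allclose(out[mids].to_numpy(), expect, atol=1e-9)

    def test_single_point_constant_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = interpolate_population({2000: 42.0})
        assert (out == 42.0).all()


def _plain_series(n_days=1000, start="2000-01-01", rate=10.0, seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    daily = pd.DataFrame({"date": dates, "deaths_all": rng.poisson(rate, n_days)})
    pop = pd.Series(1e5, index=np.unique(dates.year))
    return LocationSeries("L", "C", daily, pop)


def _event(t0, exposure_days=None):
    exposure_days = exposure_days if exposure_days is not None else [t0]
    return ExposureRecord(location="L", event_id="E", t0=t0, exposure_days=exposure_days)


class TestControlPeriods:
    def test_single_event_exclusion(self):
        s = _plain_series(1000)
        t0 = s.dates[100]
        ev = _event(t0, [t0, s.dates[101]])
        control = control_periods(s, [ev], exclusion_days=60)
        # days 100..160 excluded (61 days)
        assert len(control) == 1000 - 61
        assert t0 not in control
        assert s.dates[160] not in control
        assert s.dates[161] in control

    def test_no_events(self):
        s = _plain_series(400)
        control = control_periods(s, [])
        assert control.equals(s.dates)

    def test_overlapping_events_brute_force(self):
        s = _plain_series(1000)
        evs = [
            _event(s.dates[100], [s.dates[100], s.dates[102]]),
            _event(s.dates[130], [s.dates[130]]),
        ]
        control = control_periods(s, evs, exclusion_days=60)
        # day-by-day membership oracle
        expected = []
        for d in s.dates:
            bad = False
            for ev in evs:
                if d in ev.exposure_days:
                    bad = True
                if ev.t0 <= d <= ev.t0 + pd.Timedelta(days=60):
                    bad = True
            if not bad:
                expected.append(d)
        assert list(control) == expected

    def test_empty_control_is_error(self):
        s = _plain_series(50)
        with pytest.raises(ValueError, match="control"):
            control_periods(s, [_event(s.dates[0])], exclusion_days=60)

    @settings(max_examples=25, deadline=None)
    @given(
        t0a=st.integers(min_value=0, max_value=900),
        t0b=st.integers(min_value=0, max_value=900),
        excl=st.sampled_from([30, 60, 90]),
    )
    def test_exclusion_size_property(self, t0a, t0b, excl):
        s = _plain_series(1000, seed=1)
        evs = [_event(s.dates[t0a]), _event(s.dates[t0b])]
        control = control_periods(s, evs, exclusion_days=excl)
        windows = set()
        for t0 in (t0a, t0b):
            windows.update(range(t0, min(t0 + excl + 1, 1000)))
        assert len(control) == 1000 - len(windows)


class TestFitBaseline:
    def test_intercept_only_closed_form(self):
        s = _plain_series(1200, seed=4)
        control = s.dates[:1000]
        fit = fit_baseline(s, control, trend_knots_per_decade=None, harmonics=0, include_dow=False)
        y = s.deaths("all")[:1000]
        n_pop = s.population_daily()
        expected_rate = y.sum() / n_pop[:1000].sum()
        np.testing.assert_allclose(fit.mu.to_numpy(), n_pop * expected_rate, rtol=1e-8)

    def test_score_equation_zero(self):
        series, _ = simulate_one_location(seed=8, years=12, seasonal_amplitude=0.2)
        control = series.dates
        fit = fit_baseline(series, control)
        resid = series.deaths("all") - fit.mu.to_numpy()
        assert abs(resid.sum()) < 1e-6

    def test_seasonal_amplitude_recovery(self):
        amps = []
        for seed in range(5):
            series, _ = simulate_one_location(
                seed=seed, years=20, baseline_rate=30.0, seasonal_amplitude=0.2,
                noise_sd=0.0, noise_ar1=0.0,
            )
            fit = fit_baseline(series, series.dates)
            amp = np.hypot(fit.params["sin1"], fit.params["cos1"])
            amps.append(amp)
        assert np.mean(amps) == pytest.approx(0.2, abs=0.02)

    def test_mu_positive_everywhere_including_prediction(self):
        series, _ = simulate_one_location(seed=9, years=12)
        t0 = pd.Timestamp("2006-06-01")
        control = control_periods(series, [_event(t0)])
        fit = fit_baseline(series, control)
        assert (fit.mu > 0).all()
        assert len(fit.mu) == len(series.dates)

    def test_refit_deterministic(self):
        series, _ = simulate_one_location(seed=10, years=12)
        f1 = fit_baseline(series, series.dates)
        f2 = fit_baseline(series, series.dates)
        pd.testing.assert_series_equal(f1.mu, f2.mu)

    def test_offset_linearity(self):
        series, _ = simulate_one_location(seed=11, years=12)
        fit = fit_baseline(series, series.dates)
        doubled = LocationSeries(
            series.location, series.country, series.daily, series.population * 2.0
        )
        # at fixed coefficients the offset doubles mu
        from tcmort.baseline import _baseline_design

        X, _ = _baseline_design(series.dates, 10.0 / 7.0, 2)
        mu2 = np.exp(X @ fit.params.to_numpy() + np.log(doubled.population_daily()))
        np.testing.assert_allclose(mu2, 2.0 * fit.mu.to_numpy(), rtol=1e-12)

    def test_too_few_control_days(self):
        s = _plain_series(400)
        with pytest.raises(ValueError, match="control days"):
            fit_baseline(s, s.dates[:50])


class TestEstimateNoise:
    def test_pure_poisson(self):
        nus, sig2s = [], []
        for seed in range(10):
            series, _ = simulate_one_location(
                seed=seed, years=20, baseline_rate=20.0, seasonal_amplitude=0.3,
                noise_sd=0.0, noise_ar1=0.0,
            )
            fit = fit_baseline(series, series.dates)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nu, sigma, _ = estimate_noise(series, fit, series.dates)
            nus.append(nu)
            sig2s.append(sigma**2)
        assert np.mean(nus) == pytest.approx(1.0, abs=0.1)
        assert np.mean(sig2s) < 0.002

    def test_ar1_recovery(self):
        hits = 0
        for seed in range(10):
            series, _ = simulate_one_location(
                seed=100 + seed, years=20, baseline_rate=100.0, seasonal_amplitude=0.2,
                noise_sd=0.05, noise_ar1=0.7,
            )
            fit = fit_baseline(series, series.dates)
            _, _, ar = estimate_noise(series, fit, series.dates)
            if 0.6 <= ar[0] <= 0.8:
                hits += 1
        assert hits >= 9

    def test_degenerate_residuals(self):
        dates = pd.date_range("2000-01-01", periods=400, freq="D")
        daily = pd.DataFrame({"date": dates, "deaths_all": np.full(400, 7)})
        series = LocationSeries("L", "C", daily, pd.Series(1e5, index=np.unique(dates.year)))
        fit = BaselineFit(
            location="L", cause="all", params=pd.Series(dtype=float),
            mu=pd.Series(7.0, index=dates), design_info={},
        )
        nu, sigma, ar = estimate_noise(series, fit, dates)
        assert (nu, sigma) == (1.0, 0.0)
        assert all(a == 0.0 for a in ar)

    def test_negative_sigma_clamped(self):
        # anti-correlated artificial data: lag-1 covariance is negative, so
        # the noise variance estimate is clamped at zero
        dates = pd.date_range("2000-01-01", periods=500, freq="D")
        y = np.where(np.arange(500) % 2 == 0, 9, 11)
        daily = pd.DataFrame({"date": dates, "deaths_all": y})
        series = LocationSeries("L", "C", daily, pd.Series(1e5, index=np.unique(dates.year)))
        mu = np.full(500, 10.0)
        fit = BaselineFit(
            location="L", cause="all", params=pd.Series(dtype=float),
            mu=pd.Series(mu, index=dates), design_info={},
        )
        with pytest.warns(UserWarning):
            nu, sigma, _ = estimate_noise(series, fit, dates)
        assert sigma == 0.0


class TestLocationSeriesValidation:
    def test_date_gap_rejected(self):
        dates = pd.date_range("2000-01-01", periods=100, freq="D").delete(50)
        daily = pd.DataFrame({"date": dates, "deaths_all": np.zeros(99, dtype=int)})
        with pytest.raises(ValueError, match="contiguous"):
            LocationSeries("L", "C", daily, pd.Series(1e5, index=[2000]))

    def test_negative_deaths_rejected(self):
        dates = pd.date_range("2000-01-01", periods=10, freq="D")
        daily = pd.DataFrame({"date": dates, "deaths_all": [-1] + [0] * 9})
        with pytest.raises(ValueError, match="non-negative"):
            LocationSeries("L", "C", daily, pd.Series(1e5, index=[2000]))

    def test_missing_population_year(self):
        dates = pd.date_range("2000-01-01", periods=400, freq="D")
        daily = pd.DataFrame({"date": dates, "deaths_all": np.zeros(400, dtype=int)})
        with pytest.raises(ValueError, match="population"):
            LocationSeries("L", "C", daily, pd.Series(1e5, index=[2000]))
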