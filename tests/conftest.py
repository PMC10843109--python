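import warnings

import numpy as np
import pandas as pd
import pytest

from tcmort.baseline import LocationSeries, control_periods, estimate_noise, fit_baseline
from tcmort.synthetic import InjectedEffect, SimulationConfig, gen_location_series
from tcmort.windfield import ExposureRecord


def simulate_one_location(
    seed,
    years=15,
    baseline_rate=30.0,
    seasonal_amplitude=0.1,
    noise_sd=0.05,
    noise_ar1=0.5,
    effect=None,
    **kwargs,
):
    """One-location simulation with optional injected effect; returns (series, sim)."""
    effects = [effect] if effect is not None else []
    cfg = SimulationConfig(
        n_locations=1,
        start_year=2000,
        years=years,
        baseline_rate=baseline_rate,
        seasonal_amplitude=seasonal_amplitude,
        noise_sd=noise_sd,
        noise_ar1=noise_ar1,
        injected_effects=effects,
        seed=seed,
        **kwargs,
    )
    sim = gen_location_series(cfg)
    pop = sim.population.set_index("year")["population"]
    series = LocationSeries(location="loc000", country="X", daily=sim.daily, population=pop)
    return series, sim


def fit_one_event(series, t0, exclusion_days=60, **event_kwargs):
    """Baseline + noise + single-event fit around t0 (quiet)."""
    from tcmort.events import fit_event_effect

    ev = ExposureRecord(location=series.location, event_id="E1", t0=t0, exposure_days=[t0])
    control = control_periods(series, [ev], exclusion_days=exclusion_days)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_baseline(series, control)
        estimate_noise(series, fit, control)
        eff = fit_event_effect(series, fit, t0, event_id="E1", **event_kwargs)
    return eff, fit


@pytest.fixture(scope="session")
def rect_event_fit():
    """A fitted +30%/21-day rectangular event at mu ~ 50/day (session cache)."""
    t0 = pd.Timestamp("2007-06-15")
    effect = InjectedEffect(location="loc000", t0=t0, shape="rect", peak_pct=30.0, duration_days=21)
    series, sim = simulate_one_location(seed=42, baseline_rate=50.0, effect=effect)
    eff, fit = fit_one_event(series, t0)
    return {"effect": eff, "baseline": fit, "series": series, "truth": sim.truth[0], "t0": t0}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
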