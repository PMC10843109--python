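# tcmort

Two-stage tropical-cyclone excess-mortality analysis, exercised end-to-end
on synthetic data with known ground truth.

**Stage 0 — exposure.** Best-track storm records are rasterized to daily
maximum sustained winds on a 0.5° grid with a Holland gradient-wind profile
(shape parameter from a surface regression or supplied directly, optional
translation asymmetry, configurable surface-reduction factor and cutoff
radius). Per location, exposure days are days with cell wind ≥ 34 knots;
the hit day `t0` is the earliest such day, and each exposure record carries
the event maximum wind and cumulative rainfall around `t0`.

**Stage 1 — event effects.** Daily deaths are modelled as mixed Poisson:
`Y_t | ε_t ~ Poisson(μ_t (1 + f(t)) ε_t)`. The baseline `μ_t` (population
offset × spline trend × Fourier seasonality × day-of-week) is a Poisson GLM
fitted on control days — all days outside exposure days and post-event
exclusion windows (default 60 days, 30/90 for sensitivity). The noise ε is
characterised by a dispersion/variance decomposition and an AR(1) model
estimated from control-day residual autocovariances. The event effect
`f(t)` is a natural cubic spline (6 knots/year) plus a level jump at `t0`,
estimated by GLS under the fitted noise covariance. The period of concern
(POC) is the first contiguous post-`t0` run whose 95% CI for `f` excludes
0; excess deaths, observed/expected counts and the relative risk are
accumulated over it.

**Stage 2 — pooling.** Event-level log-RRs with delta-method SEs are
pooled by a random-intercept (location) meta-regression with known
within-row variances and REML-estimated between-location variance.
Exposure-response curves expand wind / rain / year in a natural-spline
basis (df = 2) and report `RR(x) = exp(s(x) − s(x_ref))` anchored at the
minimum observed exposure; country-level pooled RRs and temporal trends
come from stratified fits.

A synthetic-data module generates storms, gridded decadal populations,
rainfall and mortality series with injected event effects of known shape,
amplitude and duration, so every estimator above is testable offline.

## CLI

```sh
tcmort run-all --config demo.yml          # full pipeline from a YAML config
tcmort run-all --seed 1 --out out/        # built-in demo configuration
tcmort simulate --out sim/ --seed 1       # synthetic mortality only
tcmort windfield --tracks tracks.csv --out wf/ --region 10 20 120 130
tcmort validate --mortality mortality.csv --tracks tracks.csv
```

`run-all` writes every intermediate artifact (tracks, mortality,
population, exposures, events, meta dataset, ER curves, country summaries)
plus `report.json` (counts, POC summaries, pooled RRs, config hash, seed,
versions) and `MANIFEST.json` mapping each artifact to the config hash.
Reruns with the same config are byte-identical.

Config keys mirror the analysis parameters: `threshold_kn` (34),
`exclusion_days` (60; 30/90 sensitivity), `knots_per_year` (6), `meta_df`
(2), `rain_window_days` (2), plus simulation settings (region, storms,
locations, years, noise).

## Layout

- `src/tcmort/synthetic.py` — storm/population/rainfall/mortality generators + truth records
- `src/tcmort/windfield.py` — unit conversions, Holland profile, rasterization, exposure classification
- `src/tcmort/baseline.py` — population interpolation, control periods, baseline GLM, noise estimation
- `src/tcmort/events.py` — event basis, GLS effect fit, POC detection, event summaries
- `src/tcmort/meta.py` — meta dataset, REML mixed meta-regression, ER curves, country summaries
- `src/tcmort/cli.py` — pipeline orchestration, validation, click CLI
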