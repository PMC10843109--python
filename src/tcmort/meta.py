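"""Second stage: mixed-effects meta-regression of log relative risks.

Event-level log-RRs with known standard errors are pooled with a linear
mixed model — fixed covariate effects, a random intercept per location
(storms nested within locations) and between-location variance tau^2
estimated by REML. Exposure-response curves expand a covariate (wind,
rain, year) in a natural-spline basis of 2 df by default and report
RR(x) = exp(s(x) - s(x_ref)) with CIs from the fixed-effect covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._splines import natural_cubic_basis, natural_spline_df

Z95 = 1.959963984540054


def build_meta_dataset(events: pd.DataFrame, exposures: pd.DataFrame) -> pd.DataFrame:
    """Join first-stage event summaries with exposure covariates.

    ``events`` needs (event_id, location, cause, rr, rr_lo, rr_hi) and
    ``exposures`` (event_id, location, event_max_wind_kn, cumulative_rain_mm,
    year). Returns rows of (event_id, location, country, cause, logRR,
    se_logRR, wind, rain, year). The SE is reconstructed from the CI as
    (log hi - log lo) / (2 * 1.96); rows with undefined RR, inverted or
    degenerate CIs are dropped (counted in ``.attrs['n_dropped']``).
    """
    ev = events.copy()
    n0 = len(ev)
    if "rr_undefined" in ev.columns:
        ev = ev[~ev["rr_undefined"].astype(bool)]
    ev = ev[np.isfinite(ev["rr"]) & (ev["rr"] > 0)]
    inverted = ev["rr_hi"] < ev["rr_lo"]
    if inverted.any():
        warnings.warn(f"{int(inverted.sum())} rows with inverted CI rejected")
        ev = ev[~inverted]
    ev["logRR"] = np.log(ev["rr"])
    ev["se_logRR"] = (np.log(ev["rr_hi"]) - np.log(ev["rr_lo"])) / (2.0 * Z95)
    ev = ev[ev["se_logRR"] > 0]

    cols = ["event_id", "location", "event_max_wind_kn", "cumulative_rain_mm", "year"]
    merged = ev.merge(exposures[cols], on=["event_id", "location"], how="inner")
    out = merged.rename(
        columns={"event_max_wind_kn": "wind", "cumulative_rain_mm": "rain"}
    )
    if "country" not in out.columns:
        out["country"] = "ALL"
    keep = ["event_id", "location", "country", "cause", "logRR", "se_logRR", "wind", "rain", "year"]
    keep = [c for c in keep if c in out.columns]
    out = out[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = n0 - len(out)
    return out


@dataclass
class MetaFit:
    """Fitted mixed meta-regression."""

    beta: np.ndarray
    beta_cov: np.ndarray
    tau2: float
    n: int
    n_groups: int
    names: list
    reml_loglik: float
    aic: float
    tau2_boundary: bool = False
    X: np.ndarray = field(default=None, repr=False)

    def fixed_effects(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.beta_cov))
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": se,
                "lo": self.beta - Z95 * se,
                "hi": self.beta + Z95 * se,
            },
            index=self.names,
        )


def _reml_neg2(tau2, y, X, v, group_codes, n_groups):
    n, p = X.shape
    V = np.diag(v).astype(float)
    if tau2 > 0:
        for g in range(n_groups):
            idx = np.where(group_codes == g)[0]
            V[np.ix_(idx, idx)] += tau2
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    Xi = np.linalg.solve(V, X)
    XtVX = X.T @ Xi
    beta = np.linalg.solve(XtVX, Xi.T @ y)
    r = y - X @ beta
    quad = r @ np.linalg.solve(V, r)
    logdet_V = 2.0 * np.log(np.diag(L)).sum()
    sign, logdet_X = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(2 * np.pi) + logdet_V + logdet_X + quad


def fit_mixmeta(
    data: pd.DataFrame,
    fixed: list[str] | np.ndarray | None = None,
    group: str = "location",
    force_tau2: float | None = None,
) -> MetaFit:
    """Random-intercept meta-regression with known within-row variances.

    ``fixed`` names covariate columns (design gets an intercept first) or
    is a ready design matrix. tau^2 is estimated by REML via bounded
    1-D profile optimization; ``force_tau2`` pins it (0 gives the
    fixed-effects / inverse-variance fit).
    """
    y = data["logRR"].to_numpy(dtype=float)
    v = data["se_logRR"].to_numpy(dtype=float) ** 2
    if np.any(v <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("need finite logRR and positive se_logRR")
    if fixed is None:
        X = np.ones((len(y), 1))
        names = ["intercept"]
    elif isinstance(fixed, np.ndarray):
        X = np.column_stack([np.ones(len(y)), fixed])
        names = ["intercept"] + [f"x{j}" for j in range(fixed.shape[1])]
    else:
        X = np.column_stack([np.ones(len(y))] + [data[c].to_numpy(dtype=float) for c in fixed])
        names = ["intercept"] + list(fixed)
    codes, groups = pd.factorize(data[group])
    n_groups = len(groups)
    if force_tau2 is None and n_groups < 2:
        warnings.warn("fewer than 2 groups: random effect dropped (tau2 = 0)")
        force_tau2 = 0.0

    if force_tau2 is not None:
        tau2 = float(force_tau2)
        boundary = tau2 == 0.0
    else:
        upper = max(float(np.var(y)) * 4.0, float(np.max(v)) * 4.0, 1e-4)
        res = optimize.minimize_scalar(
            _reml_neg2,
            bounds=(0.0, upper),
            args=(y, X, v, codes, n_groups),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(f"REML optimization failed: {res}")
        tau2 = float(res.x)
        if _reml_neg2(0.0, y, X, v, codes, n_groups) <= res.fun + 1e-10:
            tau2 = 0.0
        boundary = tau2 < 1e-12
        if boundary:
            warnings.warn("tau2 at boundary 0: collapsing to fixed-effects fit")
            tau2 = 0.0

    V = np.diag(v).astype(float)
    if tau2 > 0:
        for g in range(n_groups):
            idx = np.where(codes == g)[0]
            V[np.ix_(idx, idx)] += tau2
    Vi_X = np.linalg.solve(V, X)
    XtVX = X.T @ Vi_X
    beta = np.linalg.solve(XtVX, Vi_X.T @ y)
    beta_cov = np.linalg.inv(XtVX)
    neg2 = _reml_neg2(tau2, y, X, v, codes, n_groups)
    # marginal ML log-likelihood at the fitted parameters, for AIC
    r = y - X @ beta
    sign, logdet_V = np.linalg.slogdet(V)
    ml_ll = -0.5 * (len(y) * np.log(2 * np.pi) + logdet_V + r @ np.linalg.solve(V, r))
    p_all = X.shape[1] + (0 if tau2 == 0 else 1)
    return MetaFit(
        beta=beta,
        beta_cov=beta_cov,
        tau2=tau2,
        n=len(y),
        n_groups=n_groups,
        names=names,
        reml_loglik=-0.5 * neg2,
        aic=-2.0 * ml_ll + 2.0 * p_all,
        tau2_boundary=boundary,
        X=X,
    )


@dataclass
class ERCurve:
    """Pooled exposure-response curve: RR over a covariate grid."""

    covariate: str
    grid: np.ndarray
    rr: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    reference: float
    extrapolated: np.ndarray
    fit: MetaFit = field(default=None, repr=False)

    def __post_init__(self):
        if not np.all((self.lo <= self.rr + 1e-12) & (self.rr <= self.hi + 1e-12)):
            raise ValueError("CI must contain the point estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariate,
                "grid": self.grid,
                "rr": self.rr,
                "lo": self.lo,
                "hi": self.hi,
                "reference": self.reference,
                "extrapolated": self.extrapolated,
            }
        )


def er_curve(
    data: pd.DataFrame,
    covariate: str,
    df: int = 2,
    grid: np.ndarray | None = None,
    reference: float | None = None,
    group: str = "location",
) -> ERCurve:
    """Univariate natural-spline (df=2 default) exposure-response curve.

    The covariate is expanded with one interior knot at its median and
    boundary knots at the 1st/99th percentiles (df=2); the reference value
    anchoring RR = 1 defaults to the minimum observed value. Grid points
    outside the observed range are flagged as extrapolation (the natural
    spline is linear there).
    """
    x = data[covariate].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in covariate {covariate}")
    basis, spec = natural_spline_df(x, df)
    fit = fit_mixmeta(data, fixed=basis, group=group)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)
    ref = float(x.min()) if reference is None else float(reference)
    extrapolated = (grid < x.min()) | (grid > x.max())
    if extrapolated.any():
        warnings.warn(f"{int(extrapolated.sum())} grid points outside the observed range")

    B_grid = natural_cubic_basis(grid, spec["interior_knots"], spec["boundary_knots"])
    B_ref = natural_cubic_basis(np.array([ref]), spec["interior_knots"], spec["boundary_knots"])
    C = B_grid - B_ref  # contrasts; intercept cancels
    b = fit.beta[1:]
    cov = fit.beta_cov[1:, 1:]
    log_rr = C @ b
    se = np.sqrt(np.einsum("ij,jk,ik->i", C, cov, C))
    return ERCurve(
        covariate=covariate,
        grid=grid,
        rr=np.exp(log_rr),
        lo=np.exp(log_rr - Z95 * se),
        hi=np.exp(log_rr + Z95 * se),
        reference=ref,
        extrapolated=extrapolated,
        fit=fit,
    )


def country_summaries(data: pd.DataFrame, min_rows: int = 3) -> pd.DataFrame:
    """Per-country pooled RR from intercept-only mixed meta fits.

    Countries with fewer than ``min_rows`` rows are reported unestimable;
    single-location countries drop the random effect (noted).
    """
    rows = []
    for country, g in data.groupby("country", sort=True):
        row = {"country": country, "n_rows": len(g), "n_locations": g["location"].nunique()}
        if len(g) < min_rows:
            row.update({"rr": np.nan, "lo": np.nan, "hi": np.nan, "tau2": np.nan, "note": "unestimable"})
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_mixmeta(g)
            fe = fit.fixed_effects().iloc[0]
            note = "random effect dropped" if row["n_locations"] < 2 else ""
            row.update(
                {
                    "rr": float(np.exp(fe["estimate"])),
                    "lo": float(np.exp(fe["lo"])),
                    "hi": float(np.exp(fe["hi"])),
                    "tau2": fit.tau2,
                    "note": note,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def temporal_trend(
    data: pd.DataFrame,
    df: int = 2,
    by_country: bool = False,
    min_rows: int = 10,
) -> dict[str, ERCurve]:
    """Year exposure-response curves, overall and optionally per country."""
    curves: dict[str, ERCurve] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curves["overall"] = er_curve(data, "year", df=df)
        if by_country:
            for country, g in data.groupby("country", sort=True):
                if len(g) < min_rows or g["year"].nunique() < df + 2:
                    continue
                curves[str(country)] = er_curve(g, "year", df=df)
    return curves
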