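"""Effort-corrected linear trends of range position, in degrees and km.

Each positional metric (centroid latitude/longitude, and for the full
range the four bounding-box limits) is regressed on year by ordinary
least squares with the matching *effort* metric — the same quantity
computed over all checklists, detections or not — as a covariate:

    position ~ year + effort_position

The year coefficient is the effort-corrected trend in degrees per year.
Collinearity between year and the effort covariate is screened with the
variance inflation factor, VIF = 1 / (1 - r^2(year, covariate)). Slopes
are converted to a cumulative displacement in kilometres over the study
window; one degree of longitude is scaled by cos(latitude) to account
for meridian convergence, using the region's mean detection-centroid
latitude as the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gridding import RegionSet

#: metric name -> (response column, covariate column, axis)
METRICS = {
    "centroid_lat": ("det_centroid_lat", "effort_centroid_lat", "lat"),
    "centroid_lon": ("det_centroid_lon", "effort_centroid_lon", "lon"),
    "limit_N": ("det_max_lat", "effort_max_lat", "lat"),
    "limit_S": ("det_min_lat", "effort_min_lat", "lat"),
    "limit_E": ("det_max_lon", "effort_max_lon", "lon"),
    "limit_W": ("det_min_lon", "effort_min_lon", "lon"),
}

CENTROID_METRICS = ("centroid_lat", "centroid_lon")

OK = "ok"
INSUFFICIENT = "insufficient"
ERROR = "error"


class CollinearityError(ValueError):
    """Effort covariate is perfectly collinear with year."""


@dataclass(frozen=True)
class KmConversion:
    """Degree-to-kilometre conversion policy.

    ``span_years`` is the inclusive count of study years (13 for
    2010-2022); multiplying the annual slope by it gives the cumulative
    displacement over the window. An interval-count policy (span 12) can
    be selected by passing ``span_years=12``. ``use_meridian_convergence``
    applies the cos(latitude) factor to longitudinal conversions; it can
    be disabled to reproduce plain equatorial-degree arithmetic.
    """

    km_per_deg_lat: float = 111.32
    span_years: int = 13
    reference_lat_policy: str = "region_mean_centroid_lat"
    fixed_reference_lat: float | None = None
    use_meridian_convergence: bool = True

    def __post_init__(self):
        if self.km_per_deg_lat <= 0:
            raise ValueError("km_per_deg_lat must be > 0")
        if self.span_years < 2:
            raise ValueError("span_years must be >= 2")
        if self.reference_lat_policy not in ("region_mean_centroid_lat", "fixed"):
            raise ValueError("unknown reference_lat_policy")

    def to_dict(self) -> dict:
        return {
            "km_per_deg_lat": self.km_per_deg_lat,
            "span_years": self.span_years,
            "reference_lat_policy": self.reference_lat_policy,
            "fixed_reference_lat": self.fixed_reference_lat,
            "use_meridian_convergence": self.use_meridian_convergence,
        }


@dataclass
class TrendResult:
    """Trend fit for one region x metric."""

    region: str
    metric: str
    status: str
    slope: float = math.nan  # degrees / year
    slope_se: float = math.nan
    p_value: float = math.nan
    adj_r2: float = math.nan
    vif: float = math.nan
    n_years: int = 0
    cumulative_km: float = math.nan
    direction: str = ""
    message: str = ""


def fit_trend(years, response, effort_covariate) -> TrendResult:
    """OLS of a positional metric on year plus its effort covariate.

    Rows with a missing value in any of the three series are dropped
    pairwise. Fewer than four complete triples yields an INSUFFICIENT
    result rather than a fit; a covariate perfectly collinear with year
    raises :class:`CollinearityError` (no slope is identifiable).
    """
    years = np.asarray(years, dtype=float)
    response = np.asarray(response, dtype=float)
    cov = np.asarray(effort_covariate, dtype=float)
    ok = np.isfinite(years) & np.isfinite(response) & np.isfinite(cov)
    years, response, cov = years[ok], response[ok], cov[ok]
    n = len(years)
    if n < 4:
        return TrendResult("", "", INSUFFICIENT, n_years=n, message=f"only {n} complete years")
    r = np.corrcoef(years, cov)[0, 1]
    r2 = float(r * r)
    if r2 >= 1.0 - 1e-12:
        raise CollinearityError("effort covariate is perfectly collinear with year")
    X = sm.add_constant(np.column_stack([years, cov]))
    fit = sm.OLS(response, X).fit()
    return TrendResult(
        region="",
        metric="",
        status=OK,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        adj_r2=float(fit.rsquared_adj),
        vif=1.0 / (1.0 - r2),
        n_years=n,
    )


def fit_trend_unadjusted(years, response) -> TrendResult:
    """OLS of position on year alone (no effort covariate).

    Used to quantify how much of a raw positional trend is attributable
    to drifting observer coverage.
    """
    years = np.asarray(years, dtype=float)
    response = np.asarray(response, dtype=float)
    ok = np.isfinite(years) & np.isfinite(response)
    years, response = years[ok], response[ok]
    n = len(years)
    if n < 3:
        return TrendResult("", "", INSUFFICIENT, n_years=n, message=f"only {n} complete years")
    X = sm.add_constant(years)
    fit = sm.OLS(response, X).fit()
    return TrendResult(
        region="",
        metric="",
        status=OK,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        adj_r2=float(fit.rsquared_adj),
        vif=1.0,
        n_years=n,
    )


def direction_label(slope: float, axis: str) -> str:
    """Compass label for a slope: N/S for latitude, E/W for longitude."""
    if not np.isfinite(slope) or slope == 0.0:
        return ""
    if axis == "lat":
        return "N" if slope > 0 else "S"
    return "E" if slope > 0 else "W"


def to_cumulative_km(
    slope: float,
    metric: str,
    conv: KmConversion | None = None,
    reference_lat: float = 0.0,
) -> float:
    """Cumulative displacement in km implied by a degrees-per-year slope.

    Latitude metrics: ``slope * span_years * km_per_deg_lat``.
    Longitude metrics additionally scale by ``cos(reference_lat)`` for
    meridian convergence (unless disabled). Sign is preserved; rounding
    is a reporting concern only.
    """
    conv = conv or KmConversion()
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}")
    axis = METRICS[metric][2]
    km = slope * conv.span_years * conv.km_per_deg_lat
    if axis == "lon" and conv.use_meridian_convergence:
        if abs(reference_lat) >= 90.0:
            raise ValueError("reference_lat must satisfy |lat| < 90")
        km *= math.cos(math.radians(reference_lat))
    return km


def _reference_lat(region_summaries: pd.DataFrame, conv: KmConversion) -> float:
    if conv.reference_lat_policy == "fixed":
        if conv.fixed_reference_lat is None:
            raise ValueError("fixed reference_lat_policy requires fixed_reference_lat")
        return conv.fixed_reference_lat
    return float(region_summaries["det_centroid_lat"].mean())


def run_all_trends(
    summaries: pd.DataFrame,
    conv: KmConversion | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every region x metric trend in the annual summary table.

    The full range gets all six metrics (centroid axes plus the four
    range limits); every other region gets the two centroid axes only.
    Per-fit failures are recorded in the ``status``/``message`` columns
    without aborting the batch. Direction labels are attached when
    ``p < alpha``, mirroring how significant shifts are reported.
    """
    conv = conv or KmConversion()
    rows = []
    for region, sub in summaries.groupby("region", sort=False):
        metrics = (
            list(METRICS) if region == RegionSet.FULL_RANGE else list(CENTROID_METRICS)
        )
        ref_lat = _reference_lat(sub, conv)
        for metric in metrics:
            resp_col, cov_col, axis = METRICS[metric]
            try:
                res = fit_trend(sub["year"], sub[resp_col], sub[cov_col])
            except CollinearityError as exc:
                res = TrendResult(region, metric, ERROR, message=str(exc))
            res.region, res.metric = region, metric
            if res.status == OK:
                res.cumulative_km = to_cumulative_km(res.slope, metric, conv, ref_lat)
                if res.p_value < alpha:
                    res.direction = direction_label(res.slope, axis)
            rows.append(res)
    return pd.DataFrame([vars(r) for r in rows])


def write_trends(trends: pd.DataFrame, path) -> None:
    """Write the trend table as tab-separated text (km to the nearest km)."""
    out = trends.copy()
    out["cumulative_km"] = out["cumulative_km"].round(0)
    for c in ("slope", "slope_se"):
        out[c] = out[c].round(6)
    for c in ("p_value", "adj_r2", "vif"):
        out[c] = out[c].round(4)
    out.to_csv(path, sep="\t", index=False)
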