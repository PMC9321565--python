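"""Trend and variability analytics on annual raster stacks.

Per-pixel ordinary-least-squares trends (year index as regressor), regional
Kendall rank trends on zonal annual series, interannual coefficient of
variation, the minimum-to-median ratio (how bad the worst year is relative
to a typical one), and zonal aggregation to arbitrary integer-coded zones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import AnnualStack, Grid, nanmedian, nanmin

DEFAULT_ALPHA = 0.05


@dataclass
class TrendMap:
    """Per-pixel linear-trend results.

    ``scaled_change`` is slope × number of study years — the change in the
    mapped quantity accumulated over the whole period — and is masked to
    pixels whose trend is significant at the chosen level.
    """

    slope: Grid
    p_value: Grid
    significant: Grid
    scaled_change: Grid
    alpha: float
    n_years: int


def pixel_trend(stack: AnnualStack, alpha: float = DEFAULT_ALPHA) -> TrendMap:
    """Vectorised per-pixel OLS of value on 0-based year index.

    The slope is the closed-form estimator Σ(t−t̄)(y−ȳ)/Σ(t−t̄)²; the
    p-value is the two-sided t-test on the slope.  Pixels with fewer than
    three valid years are nodata.  A perfect noiseless fit has p = 0; a
    constant series has slope 0 and is never significant.
    """
    arr = stack.to_array()  # (T, H, W)
    years = np.asarray(stack.years, dtype=float)
    t = years - years[0]
    valid = np.isfinite(arr)
    n = valid.sum(axis=0).astype(float)
    enough = n >= 3

    yv = np.where(valid, arr, 0.0)
    tv = np.where(valid, t[:, None, None], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tbar = tv.sum(axis=0) / n
        ybar = yv.sum(axis=0) / n
        sxy = ((tv - tbar) * (yv - ybar) * valid).sum(axis=0)
        sxx = ((tv - tbar) ** 2 * valid).sum(axis=0)
        slope = sxy / sxx
        intercept = ybar - slope * tbar
        resid = (yv - intercept - slope * tv) * valid
        sse = (resid**2).sum(axis=0)
        dof = n - 2
        se = np.sqrt(sse / dof / sxx)
        tstat = slope / se
    df_arr = np.where(dof > 0, dof, 1.0)
    p = 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(tstat), tstat, 0.0)), df_arr)
    # zero residual: perfect line → p = 0 unless the series is constant
    perfect = enough & (sse <= 1e-12 * np.maximum(np.abs(ybar), 1.0) ** 2)
    p = np.where(perfect & (np.abs(slope) > 0), 0.0, p)
    p = np.where(perfect & (np.abs(slope) == 0), 1.0, p)
    slope = np.where(enough, slope, np.nan)
    p = np.where(enough, p, np.nan)
    sig = enough & (p < alpha)
    n_years = len(stack)
    scaled = np.where(sig, slope * n_years, np.nan)

    ref = stack.geometry
    return TrendMap(
        slope=ref.like(slope),
        p_value=ref.like(p),
        significant=Grid(sig, ref.transform, ref.crs, nodata=0),
        scaled_change=ref.like(scaled),
        alpha=alpha,
        n_years=n_years,
    )


def kendall_trend(series: Sequence[float]) -> tuple[float, float]:
    """Kendall rank correlation of an annual series against time.

    Uses the tau-b tie correction; an all-equal series has no defined rank
    trend and returns (nan, nan).
    """
    y = np.asarray(series, dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    if y.size < 4:
        raise ValueError("Kendall trend needs at least 4 observations")
    if np.all(y == y[0]):
        return (float("nan"), float("nan"))
    t = np.arange(y.size, dtype=float)
    res = stats.kendalltau(t, y)
    return (float(res.statistic), float(res.pvalue))


def interannual_cv(stack: AnnualStack) -> Grid:
    """Per-pixel CV (%) = 100·sd/mean across years; nodata where mean ≤ 0."""
    arr = stack.to_array()
    valid = np.isfinite(arr)
    n = valid.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(valid, arr, 0.0).sum(axis=0) / n
        dev2 = np.where(valid, (arr - mean) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(dev2 / (n - 1))
        cv = 100.0 * sd / mean
    cv[(n < 2) | ~(mean > 0)] = np.nan
    return stack.geometry.like(cv)


def min_median_ratio(stack: AnnualStack) -> Grid:
    """Per-pixel minimum/median over years ∈ [0, 1]; nodata where median ≤ 0."""
    arr = stack.to_array()
    mn = nanmin(arr, axis=0)
    md = nanmedian(arr, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mn / md
    ratio[~(md > 0)] = np.nan
    return stack.geometry.like(ratio)


_STATISTICS = {"sum", "mean", "median", "area"}


def _zone_stat(values: np.ndarray, statistic: str, cell_area: float) -> float:
    if values.size == 0:
        return float("nan")
    if statistic == "sum":
        return float(values.sum())
    if statistic == "mean":
        return float(values.mean())
    if statistic == "median":
        return float(np.median(values))
    return float(values.size * cell_area)


def zonal_summary(
    data: AnnualStack | Grid,
    zones_grid: Grid,
    statistic: str = "mean",
    significance_levels: Sequence[float] = (0.10, 0.05, 0.01),
) -> pd.DataFrame:
    """Per-zone per-year statistic plus a Kendall trend on each zone's series.

    Zones are any integer-coded raster aligned to the data.  Returns a tidy
    table with columns ``zone, year, value, tau, p, stars`` — stars mark the
    Kendall p-value against the given significance levels (one per level
    crossed, most significant = most stars).
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
    stack = data if isinstance(data, AnnualStack) else AnnualStack(
        years=[0], layers=[data]
    )
    ref = stack.geometry
    if zones_grid.shape != ref.shape:
        raise ValueError("zones grid must match data geometry")
    zones = zones_grid.values
    zone_ids = sorted(int(z) for z in np.unique(zones[zones_grid.valid_mask]))
    cell_area = ref.cell_area

    rows = []
    for zid in zone_ids:
        in_zone = zones == zid
        series = []
        for year, grid in stack:
            vals = grid.masked()[in_zone]
            vals = vals[np.isfinite(vals)]
            series.append(_zone_stat(vals, statistic, cell_area))
        tau = p = float("nan")
        stars = ""
        finite = [v for v in series if np.isfinite(v)]
        if len(finite) >= 4 and len(finite) == len(series):
            tau, p = kendall_trend(series)
            if np.isfinite(p):
                stars = "*" * sum(p < lvl for lvl in significance_levels)
        for year, value in zip(stack.years, series):
            rows.append(
                {"zone": zid, "year": year, "value": value,
                 "tau": tau, "p": p, "stars": stars}
            )
    return pd.DataFrame(rows, columns=["zone", "year", "value", "tau", "p", "stars"])
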