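"""Trend and association statistics for interannual records.

Trends are ordinary least-squares slopes on the year index (first year
as base 0); their significance comes from the classic (non-seasonal)
Mann-Kendall test with tie correction and continuity correction, using
the normal approximation for the two-sided p-value.  Significance tiers
mirror the common map-legend convention: 99% (p<0.01), 95% (p<0.05),
90% (p<0.1).  Associations between anomaly series use Pearson
correlation with a two-sided t-based p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import stats

TIER_THRESHOLDS = ((0.01, 99), (0.05, 95), (0.10, 90))


@dataclass
class TrendResult:
    slope: float = np.nan
    intercept: float = np.nan
    mk_s: float = np.nan
    mk_var: float = np.nan
    z: float = np.nan
    p_two_sided: float = np.nan
    tier: int = 0  # 0 | 90 | 95 | 99


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def _tier(p: float) -> int:
    for thresh, tier in TIER_THRESHOLDS:
        if p < thresh:
            return tier
    return 0


def linreg_slope(years, values) -> TrendResult:
    """OLS slope and intercept with the first year as base year 0.

    Missing values are dropped pairwise; fewer than 3 finite pairs
    yields a missing result.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(years) & np.isfinite(values)
    if ok.sum() < 3:
        return TrendResult()
    t = years[ok] - years[ok].min()
    slope, intercept = np.polyfit(t, values[ok], 1)
    return TrendResult(slope=float(slope), intercept=float(intercept))


def _mk_stats(values: np.ndarray):
    """Vectorized Mann-Kendall over the last axis of a 2-D array."""
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    diff = np.sign(v[..., None, :] - v[..., :, None])  # (..., i, j): y_j - y_i
    iu = np.triu_indices(n, k=1)
    s = diff[..., iu[0], iu[1]].sum(axis=-1)

    var = np.full(v.shape[:-1], n * (n - 1) * (2 * n + 5) / 18.0)
    # tie correction per series
    flat = v.reshape(-1, n)
    var_flat = var.reshape(-1)
    for i in range(flat.shape[0]):
        _, counts = np.unique(flat[i], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            var_flat[i] -= (t * (t - 1) * (2 * t + 5)).sum() / 18.0
    var = var_flat.reshape(v.shape[:-1])

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(
            s > 0,
            (s - 1) / np.sqrt(var),
            np.where(s < 0, (s + 1) / np.sqrt(var), 0.0),
        )
    p = 2 * stats.norm.sf(np.abs(z))
    return s, var, z, p


def mann_kendall(values) -> TrendResult:
    """Classic Mann-Kendall monotonic-trend test on a single series.

    S sums the signs of all pairwise forward differences; the variance
    carries the tie correction; z uses the +/-1 continuity correction;
    the p-value is two-sided from the normal approximation.  Requires
    >= 4 finite values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        return TrendResult()
    s, var, z, p = _mk_stats(v[None, :])
    if var[0] <= 0:  # all values tied
        return TrendResult(mk_s=0.0, mk_var=0.0, z=0.0, p_two_sided=1.0, tier=0)
    return TrendResult(
        mk_s=float(s[0]),
        mk_var=float(var[0]),
        z=float(z[0]),
        p_two_sided=float(p[0]),
        tier=_tier(float(p[0])),
    )


def trend_test(years, values) -> TrendResult:
    """OLS slope plus Mann-Kendall significance on one series."""
    ols = linreg_slope(years, values)
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(years) & np.isfinite(values)
    order = np.argsort(years[ok])
    mk = mann_kendall(values[ok][order])
    return TrendResult(
        slope=ols.slope,
        intercept=ols.intercept,
        mk_s=mk.mk_s,
        mk_var=mk.mk_var,
        z=mk.z,
        p_two_sided=mk.p_two_sided,
        tier=mk.tier,
    )


def sens_slope(years, values) -> float:
    """Theil-Sen slope (median of pairwise slopes), offered as an option."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(years) & np.isfinite(values)
    if ok.sum() < 3:
        return np.nan
    res = stats.theilslopes(values[ok], years[ok])
    return float(res.slope)


def anomaly(x, dim: str | None = None):
    """Departure from the multi-year mean (per cell for stacks).

    For a 1-D array the mean is over all finite values; for an xarray
    object pass the time dimension name via ``dim``.
    """
    if isinstance(x, (xr.DataArray, xr.Dataset)):
        if dim is None:
            dim = "year" if "year" in x.dims else "time"
        return x - x.mean(dim=dim)
    x = np.asarray(x, dtype=float)
    return x - np.nanmean(x)


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided t-based p, pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return CorrelationResult(r=np.nan, p_value=np.nan, n=n)
    r, p = stats.pearsonr(x[ok], y[ok])
    return CorrelationResult(r=float(r), p_value=float(p), n=n)


def gridded_trend(stack: xr.DataArray, year_dim: str = "year") -> xr.Dataset:
    """Cell-wise OLS slope and Mann-Kendall tier over a yearly stack.

    Cells with fewer than 3 finite years are missing (tier 0, NaN
    slope); the Mann-Kendall part additionally requires 4.
    """
    years = stack[year_dim].values.astype(float)
    data = stack.transpose(year_dim, ...).values  # (year, lat, lon)
    ny = data.shape[0]
    spatial_shape = data.shape[1:]
    flat = data.reshape(ny, -1).T  # (cells, year)

    slopes = np.full(flat.shape[0], np.nan)
    tiers = np.zeros(flat.shape[0], dtype=int)
    pvals = np.full(flat.shape[0], np.nan)

    complete = np.isfinite(flat).all(axis=1)
    if complete.any() and ny >= 3:
        t = years - years.min()
        sub = flat[complete]
        tc = t - t.mean()
        slopes[complete] = (sub - sub.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
        if ny >= 4:
            _, var, _, p = _mk_stats(sub)
            good = var > 0
            pv = np.where(good, p, 1.0)
            pvals[complete] = pv
            tr = np.zeros(sub.shape[0], dtype=int)
            for thresh, tier in TIER_THRESHOLDS[::-1]:
                tr[pv < thresh] = tier
            tiers[complete] = tr

    for i in np.flatnonzero(~complete):
        res = trend_test(years, flat[i])
        slopes[i] = res.slope
        tiers[i] = res.tier
        pvals[i] = res.p_two_sided

    coords = {d: stack[d] for d in stack.dims if d != year_dim}
    dims = [d for d in stack.dims if d != year_dim]
    return xr.Dataset(
        {
            "slope": (dims, slopes.reshape(spatial_shape)),
            "tier": (dims, tiers.reshape(spatial_shape)),
            "p_value": (dims, pvals.reshape(spatial_shape)),
        },
        coords=coords,
    )
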