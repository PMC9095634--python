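"""Regional aggregation and dust-productivity association analysis.

The heavy-deposition latitude band (10-20N) of the Arabian Sea is split
into western (WAS), central (CAS) and eastern (EAS) sectors.  For each
region this module builds area-weighted interannual means, a
climatological summary (mean +/- sd per variable), percent reductions
between regions, anomaly trends with Mann-Kendall significance, and
Pearson correlations of net primary productivity (NPP) against dust
deposition flux (DDF) and surface nitrate (NIT) anomalies.

The longitude splits of the three sectors are a configurable
convention, not an observational given; defaults carve the 10-20N band
into three contiguous sectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import trends


@dataclass(frozen=True)
class RegionDef:
    name: str
    lat_bounds: tuple = (10.0, 20.0)
    lon_bounds: tuple = (50.0, 76.0)
    ocean_only: bool = True


DEFAULT_REGIONS = (
    RegionDef("WAS", (10.0, 20.0), (50.0, 58.0)),
    RegionDef("CAS", (10.0, 20.0), (58.0, 66.0)),
    RegionDef("EAS", (10.0, 20.0), (66.0, 74.0)),
)


def regional_mean(
    field: xr.DataArray, region: RegionDef, ocean_mask: xr.DataArray | None = None
) -> xr.DataArray:
    """Area-weighted (cos latitude) mean over the region's ocean cells.

    Works on (lat, lon) fields or stacks with a leading time/year
    dimension; an empty intersection raises.
    """
    sel = field.where(
        (field["lat"] >= region.lat_bounds[0])
        & (field["lat"] <= region.lat_bounds[1])
        & (field["lon"] >= region.lon_bounds[0])
        & (field["lon"] <= region.lon_bounds[1])
    )
    if ocean_mask is not None and region.ocean_only:
        sel = sel.where(ocean_mask)
    if not np.isfinite(sel.values).any():
        raise ValueError(f"region {region.name} does not intersect the field")
    w = np.cos(np.deg2rad(sel["lat"]))
    return sel.weighted(w).mean(dim=("lat", "lon"))


def reduction_percent(value_a: float, value_b: float) -> float:
    """Percent reduction 100*(a - b)/a; missing when a <= 0."""
    if not np.isfinite(value_a) or value_a <= 0:
        return np.nan
    return 100.0 * (value_a - value_b) / value_a


def climatology(series: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd per (region, variable) from a long-format series table."""
    g = series.groupby(["region", "variable"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_years="count")
    return out.reset_index()


def region_report(series: pd.DataFrame) -> dict:
    """Climatology, anomaly trends and NPP associations per region.

    ``series`` is long-format with columns region, year, variable,
    value.  Variables may span different year ranges (e.g. nitrate
    ending earlier); statistics use each variable's own years, and
    correlations use pairwise-complete years.  Returns a dict with a
    ``climatology`` table plus per-region ``trends`` (OLS slope on
    anomalies, Mann-Kendall p and tier) and ``correlations`` blocks.
    """
    required = {"region", "year", "variable", "value"}
    if not required.issubset(series.columns):
        raise ValueError(f"series table needs columns {sorted(required)}")

    report: dict = {"climatology": climatology(series), "regions": {}}
    for region, sub in series.groupby("region"):
        wide = sub.pivot_table(index="year", columns="variable", values="value")
        anom = wide - wide.mean()
        block: dict = {"trends": {}, "correlations": {}}
        for var in wide.columns:
            col = anom[var].dropna()
            if col.size < 3:
                block["trends"][var] = None
                continue
            res = trends.trend_test(col.index.values, col.values)
            block["trends"][var] = {
                "slope": res.slope,
                "p_value": res.p_two_sided,
                "tier": res.tier,
            }
        if "NPP" in anom:
            for other in anom.columns:
                if other == "NPP":
                    continue
                corr = trends.pearson(anom["NPP"].values, anom[other].values)
                block["correlations"][f"NPP-{other}"] = {
                    "r": corr.r,
                    "p_value": corr.p_value,
                    "n": corr.n,
                }
        report["regions"][region] = block
    return report


def reductions_table(climatology_df: pd.DataFrame, from_region: str, to_region: str) -> dict:
    """Percent reduction of every variable's climatological mean between regions."""
    out = {}
    for var, sub in climatology_df.groupby("variable"):
        by = sub.set_index("region")["mean"]
        if from_region in by.index and to_region in by.index:
            out[var] = reduction_percent(by[from_region], by[to_region])
    return out
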