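"""Dust retrieval: screening, depolarization partitioning, gridding.

The particulate backscatter of each screened profile is split into dust
and non-dust components from the particulate depolarization ratio (PDR)
using the standard two-component separation

    f_d = (delta - delta_nd) (1 + delta_d) / ((delta_d - delta_nd) (1 + delta)),

clipped to [0, 1], where delta_d and delta_nd are the characteristic
dust and non-dust endmember PDRs.  Dust extinction follows by scaling
the dust backscatter with the characteristic dust lidar ratio (44 sr),
and profiles are aggregated to a monthly 2x2 degree x altitude grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .grids import GridDef

KM_INV_TO_MM_INV = 1000.0  # 1 km^-1 = 1000 Mm^-1


@dataclass(frozen=True)
class RetrievalParams:
    """Endmember PDRs, dust lidar ratio and the CAD screening window.

    delta_dust / delta_nondust are the means of the typical dust
    (0.2-0.3) and non-dust (0.02-0.07) PDR ranges; lidar_ratio_dust is
    the characteristic 532 nm dust value of 44 sr; the cloud-aerosol
    discrimination (CAD) window [-100, -90] keeps confident aerosol only.
    """

    delta_dust: float = 0.25
    delta_nondust: float = 0.045
    lidar_ratio_dust: float = 44.0
    cad_window: tuple = (-100.0, -90.0)

    def __post_init__(self) -> None:
        if not self.delta_dust > self.delta_nondust >= 0:
            raise ValueError("require delta_dust > delta_nondust >= 0")
        if self.lidar_ratio_dust <= 0:
            raise ValueError("lidar_ratio_dust must be positive")


def screen(granule: xr.Dataset, params: RetrievalParams = RetrievalParams()):
    """Remove levels whose CAD score falls outside the closed window.

    Screening is applied per level; profiles left with no valid level
    are dropped.  Returns ``(screened, report)`` where report counts the
    profiles and levels affected.  An all-removed input yields an empty
    (zero-profile) dataset, not an error.
    """
    lo, hi = params.cad_window
    ok = (granule["cad_score"] >= lo) & (granule["cad_score"] <= hi)
    screened = granule.copy()
    for var in ("backscatter_532", "pdr"):
        screened[var] = granule[var].where(ok)
    keep = ok.any(dim="level")
    n_in = granule.sizes["profile"]
    screened = screened.isel(profile=np.flatnonzero(keep.values))
    report = {
        "profiles_in": int(n_in),
        "profiles_retained": int(screened.sizes["profile"]),
        "profiles_removed": int(n_in - screened.sizes["profile"]),
        "levels_removed": int((~ok).sum()),
    }
    return screened, report


def dust_fraction(pdr, params: RetrievalParams = RetrievalParams()):
    """Dust fraction of the particulate backscatter, clipped to [0, 1].

    Exactly inverts the two-component mixing rule: applied to a
    noise-free mixture with the true endmembers it returns the true
    backscatter fraction.  NaN propagates.
    """
    d_d, d_nd = params.delta_dust, params.delta_nondust
    pdr = np.asarray(pdr, dtype=float)
    if np.any(pdr[np.isfinite(pdr)] < 0):
        raise ValueError("pdr must be >= 0")
    f = (pdr - d_nd) * (1 + d_d) / ((d_d - d_nd) * (1 + pdr))
    return np.clip(f, 0.0, 1.0)


def dust_backscatter(beta_p, pdr, params: RetrievalParams = RetrievalParams()):
    """Dust component of the particulate backscatter (same units as beta_p)."""
    return np.asarray(beta_p, dtype=float) * dust_fraction(pdr, params)


def dust_extinction(beta_dust, lidar_ratio_dust: float = 44.0, to_Mm: bool = False):
    """Dust extinction = dust backscatter x dust lidar ratio.

    beta_dust in km^-1 sr^-1 gives extinction in km^-1 (or Mm^-1 with
    ``to_Mm=True``).
    """
    beta_dust = np.asarray(beta_dust, dtype=float)
    if np.any(beta_dust[np.isfinite(beta_dust)] < 0):
        raise ValueError("beta_dust must be >= 0")
    if lidar_ratio_dust <= 0:
        raise ValueError("lidar ratio must be positive")
    out = beta_dust * lidar_ratio_dust
    return out * KM_INV_TO_MM_INV if to_Mm else out


def column_dod(dext_profile, altitude_m, z_top: float = 7000.0):
    """Column dust optical depth: trapezoidal integral of extinction.

    ``dext_profile`` in km^-1 on ``altitude_m`` (metres, increasing);
    levels above ``z_top`` are excluded.  Fewer than two valid levels
    yields NaN.
    """
    alt = np.asarray(altitude_m, dtype=float)
    dext = np.asarray(dext_profile, dtype=float)
    if np.any(np.diff(alt) <= 0):
        raise ValueError("altitude must be strictly increasing")
    use = (alt <= z_top) & np.isfinite(dext)
    if use.sum() < 2:
        return np.nan
    return float(np.trapezoid(dext[use], alt[use] / 1000.0))


def partition_granule(
    granule: xr.Dataset, params: RetrievalParams = RetrievalParams()
) -> xr.Dataset:
    """Add per-level dust backscatter and extinction (km^-1) to a granule."""
    f = dust_fraction(granule["pdr"].values, params)
    beta_d = granule["backscatter_532"].values * f
    out = granule.copy()
    out["dust_fraction"] = (("profile", "level"), f)
    out["dust_backscatter"] = (("profile", "level"), beta_d)
    out["dust_extinction"] = (
        ("profile", "level"),
        dust_extinction(beta_d, params.lidar_ratio_dust),
    )
    out["dust_extinction"].attrs["units"] = "km-1"
    return out


def grid_monthly(
    granule: xr.Dataset,
    grid: GridDef = GridDef(),
    params: RetrievalParams = RetrievalParams(),
) -> xr.Dataset:
    """Aggregate partitioned profiles to the monthly 2x2 degree dust grid.

    Per cell and altitude bin, dust extinction is the arithmetic mean
    over all contributing samples; ``n_samples`` counts profiles per
    cell; cells without samples are NaN, never zero.  ``dod`` is the
    piecewise-constant column integral of the binned extinction up to
    the top altitude edge.  Profiles outside the grid are dropped and
    counted.
    """
    if "dust_extinction" not in granule:
        granule = partition_granule(granule, params)

    lats, lons = grid.lat_centers, grid.lon_centers
    edges = grid.alt_edges_m
    nbin = edges.size - 1
    ilat, ilon = grid.cell_index(granule["lat"].values, granule["lon"].values)
    inside = ilat >= 0
    n_dropped = int((~inside).sum())

    levels = granule["level"].values
    ibin = np.digitize(levels, edges) - 1
    lvl_ok = (ibin >= 0) & (ibin < nbin)

    dext = granule["dust_extinction"].values  # (profile, level)
    sums = np.zeros((lats.size, lons.size, nbin))
    cnts = np.zeros((lats.size, lons.size, nbin), dtype=int)
    nsamp = np.zeros((lats.size, lons.size), dtype=int)
    for p in np.flatnonzero(inside):
        r, c = ilat[p], ilon[p]
        nsamp[r, c] += 1
        vals = dext[p]
        good = lvl_ok & np.isfinite(vals)
        np.add.at(sums[r, c], ibin[good], vals[good])
        np.add.at(cnts[r, c], ibin[good], 1)

    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)

    dz_km = grid.alt_thickness / 1000.0
    dod = np.nansum(mean * dz_km[None, None, :], axis=2)
    dod[nsamp == 0] = np.nan

    return xr.Dataset(
        {
            "dext": (("lat", "lon", "alt_bin"), mean),
            "dod": (("lat", "lon"), dod),
            "n_samples": (("lat", "lon"), nsamp),
        },
        coords={"lat": lats, "lon": lons, "alt_bin": grid.alt_mids},
        attrs={
            "dext_units": "km-1",
            "alt_bin_units": "m",
            "alt_edges": edges.tolist(),
            "month": granule.attrs.get("month", ""),
            "profiles_dropped_outside_grid": n_dropped,
            "delta_dust": params.delta_dust,
            "delta_nondust": params.delta_nondust,
            "lidar_ratio_dust": params.lidar_ratio_dust,
        },
    )


def profile_dod_binned(granule: xr.Dataset, grid: GridDef) -> np.ndarray:
    """Per-profile DOD using the grid's altitude binning (for linearity checks)."""
    edges = grid.alt_edges_m
    nbin = edges.size - 1
    levels = granule["level"].values
    ibin = np.digitize(levels, edges) - 1
    ok = (ibin >= 0) & (ibin < nbin)
    dz_km = grid.alt_thickness / 1000.0
    dext = granule["dust_extinction"].values
    out = np.empty(granule.sizes["profile"])
    for p in range(out.size):
        vals = dext[p]
        good = ok & np.isfinite(vals)
        sums = np.zeros(nbin)
        cnts = np.zeros(nbin)
        np.add.at(sums, ibin[good], vals[good])
        np.add.at(cnts, ibin[good], 1)
        with np.errstate(invalid="ignore"):
            mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out[p] = np.nansum(mean * dz_km)
    return out
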