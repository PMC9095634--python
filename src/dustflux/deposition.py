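"""Deposition by flux divergence, loss frequency and lifetime.

Assuming no dust escapes through the top of the column and no ocean
surface source, the net convergence of the column-integrated horizontal
dust mass flux into a grid cell is the dust deposition flux (DDF,
g s^-1).  Cell-face fluxes are the arithmetic mean of the two adjacent
cell-centre column fluxes (one-sided at the domain edge), so interior
faces telescope and the domain total conserves mass exactly.  Negative
raw values are unphysical under these assumptions; they are flagged and
excluded from totals but retained for diagnostics.

Dust loss frequency (DLF, day^-1) is area-normalized DDF divided by the
dust mass loading; the assumed mass extinction efficiency cancels in
this ratio.  Dust lifetime (DLT, days) is its reciprocal.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grids import DEG, EARTH_RADIUS, G_PER_S_TO_TG_PER_YR, GridDef

SEASONS = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}


def _face_values(col: np.ndarray, axis: int) -> np.ndarray:
    """Face fluxes along ``axis``: centred average inside, one-sided at edges."""
    a = np.moveaxis(col, axis, 0)
    faces = np.empty((a.shape[0] + 1,) + a.shape[1:])
    faces[1:-1] = 0.5 * (a[:-1] + a[1:])
    faces[0] = a[0]
    faces[-1] = a[-1]
    return np.moveaxis(faces, 0, axis)


def divergence_deposition(
    flux_field: xr.Dataset,
    grid: GridDef | None = None,
    ocean_mask: np.ndarray | None = None,
) -> xr.Dataset:
    """Per-cell deposition flux from the divergence of column fluxes.

    Returns a dataset with ``ddf`` (g s^-1, negatives excluded),
    ``ddf_area`` (g m^-2 day^-1), ``raw_divergence`` (g s^-1, signed),
    ``negative_flag`` and ``boundary_flag``.  Attributes carry the
    domain totals under both bookkeepings (negatives as zero vs signed)
    and the boundary inflow/outflow, all in g s^-1 and Tg yr^-1.
    """
    lats = flux_field["lat"].values
    lons = flux_field["lon"].values
    if lats.size < 2 or lons.size < 2:
        raise ValueError("divergence undefined on a single-cell grid")
    if grid is None:
        cell = float(lats[1] - lats[0])
        grid = GridDef(
            lat_min=float(lats[0] - cell / 2),
            lat_max=float(lats[-1] + cell / 2),
            lon_min=float(lons[0] - cell / 2),
            lon_max=float(lons[-1] + cell / 2),
            cell_deg=cell,
        )

    col_u = np.nan_to_num(flux_field["column_flux_u"].values)  # (lat, lon)
    col_v = np.nan_to_num(flux_field["column_flux_v"].values)

    # zonal flux through north-south faces (length independent of lat)
    L_mer = grid.meridional_face_length()
    fu_face = _face_values(col_u, axis=1) * L_mer  # (lat, lon+1) g/s
    # meridional flux through east-west faces (length shrinks with lat)
    lat_faces = np.concatenate(
        [[lats[0] - grid.cell_deg / 2], 0.5 * (lats[:-1] + lats[1:]), [lats[-1] + grid.cell_deg / 2]]
    )
    L_zon = grid.cell_deg * EARTH_RADIUS * DEG * np.cos(lat_faces * DEG)
    fv_face = _face_values(col_v, axis=0) * L_zon[:, None]  # (lat+1, lon) g/s

    raw = (fu_face[:, :-1] - fu_face[:, 1:]) + (fv_face[:-1, :] - fv_face[1:, :])

    if ocean_mask is None:
        ocean_mask = np.ones_like(raw, dtype=bool)
    else:
        ocean_mask = np.asarray(ocean_mask, dtype=bool)
    raw = np.where(ocean_mask, raw, np.nan)

    negative = (raw < 0) & ocean_mask
    ddf = np.where(negative, 0.0, raw)

    area = grid.cell_area(lats)[:, None] * np.ones_like(raw)
    ddf_area = ddf / area * 86400.0  # g m^-2 day^-1

    boundary = np.zeros_like(raw, dtype=bool)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True

    inflow = (
        np.maximum(fu_face[:, 0], 0).sum()
        + np.maximum(-fu_face[:, -1], 0).sum()
        + np.maximum(fv_face[0, :], 0).sum()
        + np.maximum(-fv_face[-1, :], 0).sum()
    )
    outflow = (
        np.maximum(-fu_face[:, 0], 0).sum()
        + np.maximum(fu_face[:, -1], 0).sum()
        + np.maximum(-fv_face[0, :], 0).sum()
        + np.maximum(fv_face[-1, :], 0).sum()
    )

    total_clipped = float(np.nansum(ddf))
    total_signed = float(np.nansum(raw))
    out = xr.Dataset(
        {
            "ddf": (("lat", "lon"), ddf),
            "ddf_area": (("lat", "lon"), ddf_area),
            "raw_divergence": (("lat", "lon"), raw),
            "negative_flag": (("lat", "lon"), negative),
            "boundary_flag": (("lat", "lon"), boundary),
            "ocean_mask": (("lat", "lon"), ocean_mask),
        },
        coords={"lat": lats, "lon": lons},
        attrs={
            "ddf_units": "g s-1",
            "total_deposition_g_s": total_clipped,
            "total_deposition_Tg_yr": total_clipped * G_PER_S_TO_TG_PER_YR,
            "total_signed_divergence_g_s": total_signed,
            "total_signed_divergence_Tg_yr": total_signed * G_PER_S_TO_TG_PER_YR,
            "boundary_inflow_g_s": float(inflow),
            "boundary_outflow_g_s": float(outflow),
        },
    )
    return out


def loss_frequency(ddf_area, loading):
    """DLF = DDF (g m^-2 day^-1) / loading (g m^-2), in day^-1.

    DMEE cancels: DDF and loading both scale as 1/DMEE.  Cells with
    zero or missing loading are NaN.
    """
    ddf_area = np.asarray(ddf_area, dtype=float)
    loading = np.asarray(loading, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dlf = np.where(loading > 0, ddf_area / np.where(loading > 0, loading, 1.0), np.nan)
    return dlf


def lifetime(dlf):
    """DLT = 1 / DLF in days; non-positive or missing DLF yields NaN."""
    dlf = np.asarray(dlf, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(dlf > 0, 1.0 / np.where(dlf > 0, dlf, 1.0), np.nan)


def seasonal_aggregate(monthly: xr.Dataset | xr.DataArray, season: str):
    """Multi-year seasonal mean and standard deviation over a month axis.

    ``monthly`` must carry a ``time`` coordinate of numpy datetime64
    months.  Returns ``(mean, sd, coverage)`` where coverage is the
    fraction of season-months present.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; use one of {sorted(SEASONS)}")
    months = monthly["time"].dt.month
    sel = monthly.sel(time=months.isin(SEASONS[season]))
    n = sel.sizes.get("time", 0)
    if n == 0:
        raise ValueError(f"no months available for season {season}")
    mean = sel.mean(dim="time")
    sd = sel.std(dim="time", ddof=0)
    n_years = len(np.unique(monthly["time"].dt.year))
    coverage = n / (3.0 * n_years)
    return mean, sd, coverage
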