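"""Dust mass concentration and horizontal mass-flux construction.

Extinction becomes mass concentration through the dust mass extinction
efficiency (DMEE, 0.37 m^2 g^-1 at 550 nm, taken independent of altitude
and humidity); multiplying by monthly-mean wind profiles gives zonal and
meridional flux densities, layer fluxes, and column-integrated fluxes up
to 7 km, above which dust is negligible.  Every mass quantity is exactly
linear in 1/DMEE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .grids import DEG, EARTH_RADIUS, G_PER_S_TO_TG_PER_YR, GridDef


@dataclass(frozen=True)
class FluxParams:
    dmee: float = 0.37  # m^2 g^-1 at 550 nm
    z_top: float = 7000.0  # m; dust above this is negligible
    earth_radius: float = EARTH_RADIUS

    def __post_init__(self) -> None:
        if self.dmee <= 0:
            raise ValueError("dmee must be positive")
        if self.z_top <= 0:
            raise ValueError("z_top must be positive")


@dataclass(frozen=True)
class Transect:
    """A boundary line through which flux is accounted.

    ``orientation='meridional'`` is a north-south line at fixed
    longitude crossed by zonal flux; ``'zonal'`` is an east-west line at
    fixed latitude crossed by meridional flux.  ``sign=+1`` keeps the
    geographic convention: positive for eastward/northward flow.
    """

    name: str
    orientation: str  # 'meridional' | 'zonal'
    fixed_coord: float  # degrees
    span: tuple  # (min, max) degrees along the transect
    sign: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ("meridional", "zonal"):
            raise ValueError("orientation must be 'meridional' or 'zonal'")


def mass_concentration(dext, dmee: float = 0.37, dext_units: str = "km-1"):
    """Dust mass concentration DMC = DExt / DMEE in g m^-3.

    Extinction is converted to m^-1 first (``dext_units`` one of
    ``'km-1'``, ``'Mm-1'``, ``'m-1'``).
    """
    if dmee <= 0:
        raise ValueError("dmee must be positive")
    scale = {"m-1": 1.0, "km-1": 1e-3, "Mm-1": 1e-6}
    try:
        dext_m = np.asarray(dext, dtype=float) * scale[dext_units]
    except KeyError:
        raise ValueError(f"unknown extinction units {dext_units!r}") from None
    if np.any(dext_m[np.isfinite(dext_m)] < 0):
        raise ValueError("extinction must be >= 0")
    return dext_m / dmee


def flux_profiles(
    dust_grid: xr.Dataset, winds: xr.Dataset, params: FluxParams = FluxParams()
) -> xr.Dataset:
    """Build the flux field from a monthly dust grid and co-registered winds.

    Adds, on the grid's (lat, lon, alt_bin) layout:
      ``dmc`` g m^-3; ``flux_u``/``flux_v`` g m^-2 s^-1 (densities);
      ``layer_flux_u``/``_v`` g m^-1 s^-1 (density x layer thickness);
      ``column_flux_u``/``_v`` g m^-1 s^-1 (sum of layers with bin
      midpoint below z_top); ``loading`` g m^-2 (= DOD / DMEE).
    """
    for dim in ("lat", "lon", "alt_bin"):
        if not np.array_equal(dust_grid[dim].values, winds[dim].values):
            raise ValueError(
                f"winds not co-registered to dust grid on {dim}: "
                f"{winds.sizes.get(dim)} vs {dust_grid.sizes.get(dim)}"
            )
    units = dust_grid.attrs.get("dext_units", "km-1")
    dmc = mass_concentration(dust_grid["dext"].values, params.dmee, units)

    mids = dust_grid["alt_bin"].values
    edges = dust_grid.attrs.get("alt_edges")
    if edges is not None:
        dz = np.diff(np.asarray(edges, dtype=float))
    elif mids.size >= 2:
        dz = np.gradient(mids)  # uniform-bin approximation
    else:
        raise ValueError(
            "single altitude bin without alt_edges metadata: thickness unknown"
        )
    below = mids < params.z_top

    fu = dmc * winds["u"].values
    fv = dmc * winds["v"].values
    layer_u = fu * dz[None, None, :]
    layer_v = fv * dz[None, None, :]
    col_u = np.nansum(np.where(below[None, None, :], layer_u, 0.0), axis=2)
    col_v = np.nansum(np.where(below[None, None, :], layer_v, 0.0), axis=2)
    valid = np.isfinite(dmc).any(axis=2)
    col_u[~valid] = np.nan
    col_v[~valid] = np.nan
    loading = np.nansum(dmc * dz[None, None, :], axis=2)
    loading[~valid] = np.nan

    out = dust_grid.copy()
    out["dmc"] = (("lat", "lon", "alt_bin"), dmc)
    out["flux_u"] = (("lat", "lon", "alt_bin"), fu)
    out["flux_v"] = (("lat", "lon", "alt_bin"), fv)
    out["layer_flux_u"] = (("lat", "lon", "alt_bin"), layer_u)
    out["layer_flux_v"] = (("lat", "lon", "alt_bin"), layer_v)
    out["column_flux_u"] = (("lat", "lon"), col_u)
    out["column_flux_v"] = (("lat", "lon"), col_v)
    out["loading"] = (("lat", "lon"), loading)
    out.attrs["dmee"] = params.dmee
    out.attrs["z_top"] = params.z_top
    return out


def transect_flux(
    flux_field: xr.Dataset, transect: Transect, cell_deg: float | None = None
) -> dict:
    """Signed flux through a transect, per altitude bin and total, Tg yr^-1.

    The layer flux density of the cell column nearest the fixed
    coordinate is multiplied by the cell face length and summed along
    the transect span; cells with missing flux reduce the reported
    coverage fraction.
    """
    lats = flux_field["lat"].values
    lons = flux_field["lon"].values
    if cell_deg is None:
        cell_deg = float(lats[1] - lats[0]) if lats.size > 1 else 2.0

    if transect.orientation == "meridional":
        j = int(np.argmin(np.abs(lons - transect.fixed_coord)))
        sel = (lats >= transect.span[0]) & (lats <= transect.span[1])
        if not sel.any():
            raise ValueError("transect span outside grid")
        layer = flux_field["layer_flux_u"].values[sel, j, :]  # (cells, bin)
        face_len = np.full(sel.sum(), cell_deg * EARTH_RADIUS * DEG)
    else:
        i = int(np.argmin(np.abs(lats - transect.fixed_coord)))
        sel = (lons >= transect.span[0]) & (lons <= transect.span[1])
        if not sel.any():
            raise ValueError("transect span outside grid")
        layer = flux_field["layer_flux_v"].values[i, sel, :]
        face_len = cell_deg * EARTH_RADIUS * DEG * np.cos(lats[i] * DEG) * np.ones(sel.sum())

    valid = np.isfinite(layer).all(axis=1)
    per_bin_g_s = np.nansum(layer[valid] * face_len[valid, None], axis=0)
    per_bin = transect.sign * per_bin_g_s * G_PER_S_TO_TG_PER_YR
    return {
        "name": transect.name,
        "per_bin_Tg_yr": per_bin,
        "total_Tg_yr": float(per_bin.sum()),
        "coverage": float(valid.mean()),
        "alt_bin_m": flux_field["alt_bin"].values,
    }


def scenario_flux_field(scenario) -> xr.Dataset:
    """Wrap a PlumeScenario's prescribed fields as a flux-field dataset."""
    g: GridDef = scenario.grid
    mids = g.alt_mids
    dz = g.alt_thickness
    fu = scenario.concentration * scenario.winds_u
    fv = scenario.concentration * scenario.winds_v
    return xr.Dataset(
        {
            "dmc": (("lat", "lon", "alt_bin"), scenario.concentration),
            "flux_u": (("lat", "lon", "alt_bin"), fu),
            "flux_v": (("lat", "lon", "alt_bin"), fv),
            "layer_flux_u": (("lat", "lon", "alt_bin"), fu * dz[None, None, :]),
            "layer_flux_v": (("lat", "lon", "alt_bin"), fv * dz[None, None, :]),
            "column_flux_u": (("lat", "lon"), scenario.column_flux_u),
            "column_flux_v": (("lat", "lon"), scenario.column_flux_v),
            "loading": (
                ("lat", "lon"),
                np.sum(scenario.concentration * dz[None, None, :], axis=2),
            ),
        },
        coords={"lat": g.lat_centers, "lon": g.lon_centers, "alt_bin": mids},
    )
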