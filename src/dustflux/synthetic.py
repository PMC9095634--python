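"""Synthetic inputs with analytically known answers.

Three generators stand in for the observational record so that every
downstream stage can be tested against ground truth:

* :func:`make_granule` -- lidar-like granules of particulate backscatter
  and particulate depolarization ratio (PDR), built as two-component
  dust / non-dust mixtures so the retrieval's partitioning is exactly
  invertible at zero noise.
* :func:`make_plume` -- gridded dust plumes advected by prescribed winds
  with a closed-form flux divergence, the oracle for the deposition
  estimator (mass closure holds exactly).
* :func:`make_series` -- regional interannual series with prescribed
  linear trends and cross-correlations, the fixture for the trend and
  correlation statistics.

All generators are seed-deterministic: the same spec yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridDef

# -- lidar granules ---------------------------------------------------------

DEFAULT_ALTITUDE_GRID = tuple(np.arange(0.0, 10001.0, 60.0))  # m, CALIOP-like


@dataclass(frozen=True)
class GranuleSpec:
    """Recipe for a synthetic nighttime lidar granule.

    Dust occupies the prescribed layers with extinction in km^-1; a
    spherical (non-dust) background fills the column.  The composite PDR
    of each level follows the standard two-component backscatter mixing
    rule, which is the exact inverse of the retrieval's partitioning.
    """

    n_profiles: int = 100
    lat_range: tuple = (10.0, 20.0)
    lon_range: tuple = (50.0, 70.0)
    altitude_grid: tuple = DEFAULT_ALTITUDE_GRID
    dust_layers: tuple = ((500.0, 3500.0, 0.1),)  # (base m, top m, ext km^-1)
    nondust_background: float = 0.01  # km^-1
    delta_dust_true: float = 0.25
    delta_nondust_true: float = 0.045
    lidar_ratio_dust: float = 44.0  # sr
    lidar_ratio_nondust: float = 25.0  # sr, typical marine aerosol
    cad_outlier_fraction: float = 0.0
    noise_sd_rel: float = 0.0
    month: str = "2007-06"
    seed: int = 0

    def __post_init__(self) -> None:
        alt = np.asarray(self.altitude_grid, dtype=float)
        if alt.size == 0:
            raise ValueError("altitude grid must not be empty")
        if np.any(np.diff(alt) <= 0):
            raise ValueError("altitude grid must be strictly increasing")
        for base, top, ext in self.dust_layers:
            if ext < 0:
                raise ValueError("dust layer extinction must be >= 0")
            if top <= base:
                raise ValueError("dust layer top must exceed base")
        if self.nondust_background < 0:
            raise ValueError("background extinction must be >= 0")
        for d in (self.delta_dust_true, self.delta_nondust_true):
            if not 0 <= d < 1:
                raise ValueError("PDR endmembers must lie in [0, 1)")
        if not 0 <= self.cad_outlier_fraction <= 1:
            raise ValueError("cad_outlier_fraction must lie in [0, 1]")


def mix_pdr(beta_dust, beta_nondust, delta_dust, delta_nondust):
    """Composite PDR of a two-component backscatter mixture.

    Mixing is linear in the co-polar backscatter beta/(1+delta):

        delta = (b_d d_d/(1+d_d) + b_nd d_nd/(1+d_nd))
                / (b_d/(1+d_d) + b_nd/(1+d_nd))
    """
    num = beta_dust * delta_dust / (1 + delta_dust) + beta_nondust * delta_nondust / (
        1 + delta_nondust
    )
    den = beta_dust / (1 + delta_dust) + beta_nondust / (1 + delta_nondust)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def make_granule(spec: GranuleSpec) -> xr.Dataset:
    """Generate a granule of screened-quality profiles plus truth arrays.

    Returns a dataset with dims ``(profile, level)`` and variables
    ``backscatter_532`` (km^-1 sr^-1), ``pdr``, ``cad_score``, ``lat``,
    ``lon``, ``time``, together with the noise-free truth fields
    ``dust_fraction_true`` (backscatter fraction) and
    ``dust_extinction_true`` (km^-1) used only by tests.
    """
    rng = np.random.default_rng(spec.seed)
    alt = np.asarray(spec.altitude_grid, dtype=float)
    nz = alt.size
    n = int(spec.n_profiles)

    alpha_dust = np.zeros(nz)
    for base, top, ext in spec.dust_layers:
        alpha_dust[(alt >= base) & (alt <= top)] += ext
    alpha_nondust = np.full(nz, float(spec.nondust_background))

    beta_dust = alpha_dust / spec.lidar_ratio_dust
    beta_nondust = alpha_nondust / spec.lidar_ratio_nondust
    beta_total = beta_dust + beta_nondust
    pdr_clean = mix_pdr(
        beta_dust, beta_nondust, spec.delta_dust_true, spec.delta_nondust_true
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_true = np.where(beta_total > 0, beta_dust / np.where(beta_total > 0, beta_total, 1.0), 0.0)

    beta = np.tile(beta_total, (n, 1))
    pdr = np.tile(pdr_clean, (n, 1))
    if spec.noise_sd_rel > 0:
        # mean-one multiplicative log-normal on backscatter, additive Gaussian
        # on PDR; the -s^2/2 shift keeps noisy sample means unbiased
        s = spec.noise_sd_rel
        beta = beta * np.exp(rng.normal(-0.5 * s * s, s, size=beta.shape))
        pdr = pdr + rng.normal(0.0, spec.noise_sd_rel * np.maximum(pdr, 1e-3))
        pdr = np.clip(pdr, 0.0, 0.8)

    # confident-aerosol CAD in [-100, -90]; outliers get an ambiguous score
    cad = np.full((n, nz), -95.0)
    n_out = int(round(spec.cad_outlier_fraction * n))
    outliers = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    cad[outliers, :] = -50.0

    lat = rng.uniform(*spec.lat_range, size=n)
    lon = rng.uniform(*spec.lon_range, size=n)
    time = np.full(n, np.datetime64(spec.month, "M"))

    ds = xr.Dataset(
        {
            "backscatter_532": (("profile", "level"), beta),
            "pdr": (("profile", "level"), pdr),
            "cad_score": (("profile", "level"), cad),
            "lat": ("profile", lat),
            "lon": ("profile", lon),
            "time": ("profile", time),
            "dust_fraction_true": ("level", frac_true),
            "dust_extinction_true": ("level", alpha_dust),
        },
        coords={"level": alt},
        attrs={
            "month": spec.month,
            "delta_dust_true": spec.delta_dust_true,
            "delta_nondust_true": spec.delta_nondust_true,
            "lidar_ratio_dust": spec.lidar_ratio_dust,
            "backscatter_units": "km-1 sr-1",
            "level_units": "m",
        },
    )
    ds["cad_outlier_profiles"] = ("outlier", np.sort(outliers))
    return ds


# -- advected plumes with analytic deposition -------------------------------


@dataclass
class PlumeScenario:
    """A steady dust plume on a lat/lon grid with known deposition.

    ``truth_deposition`` (g s^-1 per cell) is minus the divergence of the
    column-integrated horizontal mass flux, evaluated from exact face
    fluxes of the prescribed fields, so domain-total deposition equals
    boundary inflow minus outflow to 64-bit rounding.
    """

    grid: GridDef
    concentration: np.ndarray  # (lat, lon, layer) g m^-3
    winds_u: np.ndarray  # (lat, lon, layer) m s^-1
    winds_v: np.ndarray
    column_flux_u: np.ndarray  # (lat, lon) g m^-1 s^-1 at cell centres
    column_flux_v: np.ndarray
    truth_deposition: np.ndarray  # (lat, lon) g s^-1
    boundary_inflow: float  # g s^-1
    boundary_outflow: float

    def mass_closure_report(self) -> dict:
        total = float(self.truth_deposition.sum())
        net = self.boundary_inflow - self.boundary_outflow
        return {
            "total_truth_deposition_g_s": total,
            "boundary_net_g_s": net,
            "closure_residual_g_s": total - net,
        }


def _gaussian_column_flux(grid: GridDef, c0, lon0, sigma_deg, u0, dz):
    """Column flux density u0*C(lon)*dz for a zonal Gaussian ridge."""

    def f(lon):
        return u0 * c0 * np.exp(-((lon - lon0) ** 2) / (2 * sigma_deg**2)) * dz

    return f


def make_plume(kind: str, **params) -> PlumeScenario:
    """Build a plume scenario of the requested ``kind``.

    kinds:
      ``uniform_advection`` -- uniform concentration and wind; zero
      divergence, zero deposition everywhere.
      ``gaussian_plume`` -- concentration Gaussian in longitude, uniform
      zonal wind; the sink is the analytic flux difference across each
      pair of cell faces.  The Gaussian centre defaults to the upwind
      (western) domain edge so the in-domain flux decays monotonically
      downwind and the divergence sink is positive everywhere, like a
      plume losing mass to deposition during transport.

    params (all optional): ``grid`` (GridDef), ``c0`` g m^-3, ``u0`` m/s,
    ``lon0``/``sigma_deg`` degrees (gaussian only).
    """
    grid: GridDef = params.pop("grid", GridDef())
    c0 = float(params.pop("c0", 1e-5))
    u0 = float(params.pop("u0", 10.0))
    lon0 = float(params.pop("lon0", grid.lon_min))
    sigma_deg = float(params.pop("sigma_deg", (grid.lon_max - grid.lon_min) / 4))
    if params:
        raise TypeError(f"unknown plume parameters: {sorted(params)}")
    if not (np.isfinite(c0) and np.isfinite(u0)):
        raise ValueError("winds and concentration must be finite")

    lats, lons = grid.lat_centers, grid.lon_centers
    nlat, nlon, nlay = lats.size, lons.size, grid.alt_mids.size
    dz_total = float(grid.alt_edges_m[-1] - grid.alt_edges_m[0])
    L_mer = grid.meridional_face_length()
    half = grid.cell_deg / 2

    winds_u = np.full((nlat, nlon, nlay), u0)
    winds_v = np.zeros((nlat, nlon, nlay))

    if kind == "uniform_advection":
        conc = np.full((nlat, nlon, nlay), c0)
        col_u = np.full((nlat, nlon), u0 * c0 * dz_total)
        flux_at = lambda lon: u0 * c0 * dz_total  # noqa: E731
    elif kind == "gaussian_plume":
        prof = c0 * np.exp(-((lons - lon0) ** 2) / (2 * sigma_deg**2))
        conc = np.broadcast_to(prof[None, :, None], (nlat, nlon, nlay)).copy()
        flux_at = _gaussian_column_flux(grid, c0, lon0, sigma_deg, u0, dz_total)
        col_u = np.broadcast_to(flux_at(lons)[None, :], (nlat, nlon)).copy()
    else:
        raise ValueError(f"unknown plume kind: {kind!r}")

    col_v = np.zeros((nlat, nlon))

    # exact face fluxes: flow varies only in longitude, v = 0
    face_w = np.array([flux_at(lon - half) for lon in lons]) * L_mer  # g/s per row cell
    face_e = np.array([flux_at(lon + half) for lon in lons]) * L_mer
    truth = np.broadcast_to((face_w - face_e)[None, :], (nlat, nlon)).copy()

    inflow = float(nlat * max(face_w[0], 0.0) + nlat * max(-face_e[-1], 0.0))
    outflow = float(nlat * max(face_e[-1], 0.0) + nlat * max(-face_w[0], 0.0))

    return PlumeScenario(
        grid=grid,
        concentration=conc,
        winds_u=winds_u,
        winds_v=winds_v,
        column_flux_u=col_u,
        column_flux_v=col_v,
        truth_deposition=truth,
        boundary_inflow=inflow,
        boundary_outflow=outflow,
    )


# -- regional interannual series --------------------------------------------


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for correlated interannual series with linear trends.

    Noise across variables is equicorrelated at ``cross_corr`` via a
    common-factor construction, so any pair of variables attains the
    target Pearson correlation in expectation.
    """

    n_years: int = 14  # 2007-2020
    start_year: int = 2007
    slopes: Mapping[str, float] = field(
        default_factory=lambda: {"NPP": -5.8, "DDF": -0.2, "NIT": -0.1}
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"NPP": 30.0, "DDF": 1.0, "NIT": 0.5}
    )
    cross_corr: float = 0.73
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("need at least 3 years")
        if abs(self.cross_corr) > 1:
            raise ValueError("|cross_corr| must be <= 1")


def make_series(spec: SeriesSpec) -> pd.DataFrame:
    """Long-format DataFrame with columns ``year``, ``variable``, ``value``.

    Each variable k is slope_k * t + noise_sd_k * e_k with t = 0..n-1 and
    e drawn from an equicorrelated Gaussian (correlation ``cross_corr``
    between every pair, via Cholesky factorization).
    """
    rng = np.random.default_rng(spec.seed)
    names: Sequence[str] = list(spec.slopes)
    m = len(names)
    rho = spec.cross_corr
    corr = np.full((m, m), rho)
    np.fill_diagonal(corr, 1.0)
    # eigen factorization tolerates the PSD boundary (|rho| = 1)
    evals, evecs = np.linalg.eigh(corr)
    if evals.min() < -1e-8:
        raise ValueError(f"cross_corr {rho} is not attainable for {m} variables")
    factor = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    t = np.arange(spec.n_years)
    z = rng.standard_normal((m, spec.n_years))
    e = factor @ z
    rows = []
    for k, name in enumerate(names):
        vals = spec.slopes[name] * t + spec.noise_sd.get(name, 0.0) * e[k]
        for yr, v in zip(spec.start_year + t, vals):
            rows.append((int(yr), name, float(v)))
    return pd.DataFrame(rows, columns=["year", "variable", "value"])


def make_winds(
    grid: GridDef, u0: float = 5.0, v0: float = 0.0, shear_per_km: float = 0.0
) -> xr.Dataset:
    """Monthly-mean wind profiles on the dust grid (single month).

    Optionally adds a linear vertical shear (m/s per km of altitude) to
    the zonal component, mimicking the low-level jet structure.
    """
    lats, lons = grid.lat_centers, grid.lon_centers
    mids = grid.alt_mids
    u = u0 + shear_per_km * mids / 1000.0
    uu = np.broadcast_to(u[None, None, :], (lats.size, lons.size, mids.size)).copy()
    vv = np.full((lats.size, lons.size, mids.size), v0)
    return xr.Dataset(
        {"u": (("lat", "lon", "alt_bin"), uu), "v": (("lat", "lon", "alt_bin"), vv)},
        coords={"lat": lats, "lon": lons, "alt_bin": mids},
        attrs={"units": "m s-1", "alt_bin_units": "m"},
    )
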