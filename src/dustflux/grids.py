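"""Grid geometry shared by the retrieval, flux and deposition stages.

All gridded products live on a regular latitude/longitude grid of
cell centres (degrees north/east) with uniform spacing, plus a set of
altitude bins (metres above mean sea level).  Face lengths use a
spherical Earth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS = 6.371e6  # m
DEG = np.pi / 180.0
SECONDS_PER_YEAR = 3.1536e7  # 365-day year, matches Tg yr-1 annualization
G_PER_S_TO_TG_PER_YR = SECONDS_PER_YEAR * 1e-12


@dataclass(frozen=True)
class GridDef:
    """Regular lat/lon grid with altitude bins.

    Defaults describe the Arabian Sea study domain (0-40N, 30-76E) at
    2x2 degree resolution with 1 km altitude bins from the surface to
    7 km, above which dust is treated as negligible.
    """

    lat_min: float = 0.0
    lat_max: float = 40.0
    lon_min: float = 30.0
    lon_max: float = 76.0
    cell_deg: float = 2.0
    alt_edges: tuple = field(default=tuple(np.arange(0.0, 7001.0, 1000.0)))

    def __post_init__(self) -> None:
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("grid bounds must be increasing")
        if self.cell_deg <= 0:
            raise ValueError("cell_deg must be positive")
        edges = np.asarray(self.alt_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("alt_edges must be increasing with >= 2 entries")

    @property
    def lat_centers(self) -> np.ndarray:
        return np.arange(self.lat_min + self.cell_deg / 2, self.lat_max, self.cell_deg)

    @property
    def lon_centers(self) -> np.ndarray:
        return np.arange(self.lon_min + self.cell_deg / 2, self.lon_max, self.cell_deg)

    @property
    def alt_edges_m(self) -> np.ndarray:
        return np.asarray(self.alt_edges, dtype=float)

    @property
    def alt_mids(self) -> np.ndarray:
        e = self.alt_edges_m
        return 0.5 * (e[:-1] + e[1:])

    @property
    def alt_thickness(self) -> np.ndarray:
        return np.diff(self.alt_edges_m)

    def meridional_face_length(self) -> float:
        """Length (m) of a north-south cell face, crossed by zonal flux."""
        return self.cell_deg * EARTH_RADIUS * DEG

    def zonal_face_length(self, lat_deg) -> np.ndarray:
        """Length (m) of an east-west cell face at latitude ``lat_deg``."""
        return self.cell_deg * EARTH_RADIUS * DEG * np.cos(np.asarray(lat_deg) * DEG)

    def cell_area(self, lat_deg) -> np.ndarray:
        """Cell area (m^2) on the sphere at cell-centre latitude."""
        dlam = self.cell_deg * DEG
        lat = np.asarray(lat_deg, dtype=float) * DEG
        half = self.cell_deg * DEG / 2
        return EARTH_RADIUS**2 * dlam * (np.sin(lat + half) - np.sin(lat - half))

    def cell_index(self, lat, lon):
        """Map point coordinates to (ilat, ilon); -1 marks out-of-domain."""
        ilat = np.floor((np.asarray(lat) - self.lat_min) / self.cell_deg).astype(int)
        ilon = np.floor((np.asarray(lon) - self.lon_min) / self.cell_deg).astype(int)
        bad = (
            (ilat < 0)
            | (ilat >= self.lat_centers.size)
            | (ilon < 0)
            | (ilon >= self.lon_centers.size)
        )
        ilat = np.where(bad, -1, ilat)
        ilon = np.where(bad, -1, ilon)
        return ilat, ilon
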