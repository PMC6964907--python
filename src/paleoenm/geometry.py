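"""Grid geometry and geodesic helpers shared across the package.

All coordinates are geographic (longitude/latitude, decimal degrees, WGS84).
Distances are great-circle (haversine) on a sphere of mean radius
6371.0088 km.  Rasters use cell-center registration with row 0 as the
northernmost row, matching the ESRI ASCII grid convention used for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM: float = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats):
    """Full symmetric distance matrix (km) for a set of points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


@dataclass(frozen=True)
class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection about a center point.

    Distances from the center are exact great-circle distances; this is the
    standard choice for buffering a point set by a km radius when the data
    live in geographic coordinates.  Units of the projected plane are km.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        lon0 = np.radians(self.lon0)
        lat0 = np.radians(self.lat0)
        cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
        c = np.arccos(np.clip(cos_c, -1.0, 1.0))
        # k = c / sin(c), with the removable singularity at the center
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0)
        y = EARTH_RADIUS_KM * k * (
            np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0)
        )
        return x, y


@dataclass(frozen=True)
class GridGeometry:
    """Raster grid geometry: lower-left corner, square cells, row 0 north.

    ``xll``/``yll`` are the corner coordinates of the lower-left cell (ESRI
    ``xllcorner``/``yllcorner``), ``cellsize`` in decimal degrees.
    """

    xll: float
    yll: float
    cellsize: float
    n_rows: int
    n_cols: int
    nodata: float = -9999.0

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    # -- cell centers ------------------------------------------------------
    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.n_cols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        # row 0 is the northernmost row
        return self.yll + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cellsize

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.xll + (col + 0.5) * self.cellsize,
            self.yll + (self.n_rows - row - 0.5) * self.cellsize,
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) at cell centers."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    # -- extent and lookup -------------------------------------------------
    @property
    def x_max(self) -> float:
        return self.xll + self.n_cols * self.cellsize

    @property
    def y_max(self) -> float:
        return self.yll + self.n_rows * self.cellsize

    def contains(self, lon: float, lat: float) -> bool:
        return self.xll <= lon < self.x_max and self.yll <= lat < self.y_max

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent")
        col = int((lon - self.xll) / self.cellsize)
        row = self.n_rows - 1 - int((lat - self.yll) / self.cellsize)
        return row, col

    def cells_of(self, lons, lats) -> tuple[np.ndarray, np.ndarray]:
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        inside = (
            (lons >= self.xll)
            & (lons < self.x_max)
            & (lats >= self.yll)
            & (lats < self.y_max)
        )
        if not np.all(inside):
            raise ValueError("some points fall outside the grid extent")
        cols = ((lons - self.xll) / self.cellsize).astype(int)
        rows = self.n_rows - 1 - ((lats - self.yll) / self.cellsize).astype(int)
        return rows, cols

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )
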