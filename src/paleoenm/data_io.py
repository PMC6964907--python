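"""Occurrence tables and bioclimatic raster stacks.

Occurrences are per-species, per-season point records (longitude/latitude,
WGS84) read from CSV.  Climate comes as a stack of the 19 bioclimatic
variables (BIO1-BIO19), one raster per variable, all co-registered; rasters
are read and written as ESRI ASCII grids.  The filters in this module are
the standard locality-preparation steps for presence-background niche
modeling over continental extents: a longitude cutoff restricting records
to the region relevant to the focal site, nearest-neighbor spatial thinning
to reduce sampling bias, and random subsampling of very dense record sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GridGeometry, pairwise_haversine_km

N_BIOCLIM = 19

BREEDING = "breeding"
WINTER = "winter"
SEASONS = (BREEDING, WINTER)


class EmptyInputError(ValueError):
    """Raised when an ingest or filter step leaves zero usable records."""


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Point records for one species in one season.

    ``records`` has columns ``lon``, ``lat``, ``source``; exact-duplicate
    coordinate pairs are removed on construction.  ``attrs`` carries
    provenance such as ingest drop counts.
    """

    species_id: str
    season: str
    records: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        df = self.records
        for col in ("lon", "lat"):
            if col not in df.columns:
                raise ValueError(f"records missing required column {col!r}")
        if "source" not in df.columns:
            df = df.assign(source="")
        if ((df["lon"] < -180) | (df["lon"] > 180)).any():
            raise ValueError("longitudes must lie in [-180, 180]")
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise ValueError("latitudes must lie in [-90, 90]")
        self.records = df.drop_duplicates(subset=["lon", "lat"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return self.records["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.records["lat"].to_numpy(dtype=float)

    def _with(self, df: pd.DataFrame, **attrs) -> "OccurrenceSet":
        new = replace(self, records=df.reset_index(drop=True))
        new.attrs = {**self.attrs, **attrs}
        return new


def read_occurrences(
    path: str | Path,
    species_id: str,
    season: str,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    source_col: str | None = None,
) -> OccurrenceSet:
    """Read a CSV of point records, dropping unusable rows with a count.

    Rows with unparsable or out-of-range coordinates are dropped; exact
    duplicate coordinate pairs are collapsed.  Drop counts are recorded in
    ``attrs['ingest_report']``.  Raises :class:`EmptyInputError` if nothing
    survives.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    for col in (lon_col, lat_col):
        if col not in raw.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    lon = pd.to_numeric(raw[lon_col], errors="coerce")
    lat = pd.to_numeric(raw[lat_col], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    n_bad = int((~ok).sum())
    df = pd.DataFrame(
        {
            "lon": lon[ok].to_numpy(dtype=float),
            "lat": lat[ok].to_numpy(dtype=float),
            "source": raw.loc[ok, source_col].astype(str).to_numpy() if source_col else "",
        }
    )
    n_valid = len(df)
    df = df.drop_duplicates(subset=["lon", "lat"])
    report = {
        "n_raw": len(raw),
        "n_dropped_invalid": n_bad,
        "n_dropped_duplicate": n_valid - len(df),
        "n_kept": len(df),
    }
    if len(df) == 0:
        raise EmptyInputError(f"no valid records in {path}")
    return OccurrenceSet(species_id, season, df.reset_index(drop=True), {"ingest_report": report})


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    """Write records in the same dialect ``read_occurrences`` expects."""
    df = pd.DataFrame(
        {
            "species": occ.species_id,
            "longitude": occ.lons,
            "latitude": occ.lats,
            "source": occ.records["source"],
        }
    )
    df.to_csv(path, index=False)


def filter_west_of(occ: OccurrenceSet, lon_cutoff: float) -> OccurrenceSet:
    """Keep records strictly west of ``lon_cutoff`` (order preserved)."""
    if not -180 <= lon_cutoff <= 180:
        raise ValueError("lon_cutoff must lie in [-180, 180]")
    keep = occ.records["lon"] < lon_cutoff
    out = occ._with(occ.records[keep], lon_cutoff=lon_cutoff)
    if len(out) == 0:
        out.attrs["empty_after_filter"] = True
    return out


def thin_occurrences(occ: OccurrenceSet, min_km: float, seed: int) -> OccurrenceSet:
    """Thin records so that all pairwise great-circle distances exceed ``min_km``.

    Iteratively removes the record with the most neighbors within ``min_km``
    until no violating pair remains; ties are broken by position in a
    seed-fixed shuffle, so the result is deterministic per seed.  Output is
    a subset of the input, in the original record order.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    n = len(occ)
    if n <= 1:
        return occ._with(occ.records, thin_min_km=min_km)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)  # tie-break priority: earlier in shuffle wins removal
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    dist = pairwise_haversine_km(occ.lons, occ.lats)
    close = (dist <= min_km)
    np.fill_diagonal(close, False)
    alive = np.ones(n, dtype=bool)
    counts = close.sum(axis=1)
    while True:
        active = np.flatnonzero(alive & (counts > 0))
        if active.size == 0:
            break
        worst = counts[active].max()
        cand = active[counts[active] == worst]
        victim = cand[np.argmin(rank[cand])]
        alive[victim] = False
        counts[close[victim]] -= 1
        counts[victim] = 0
    out = occ._with(occ.records[alive], thin_min_km=min_km, thin_seed=seed)
    return out


def subsample(occ: OccurrenceSet, max_n: int, seed: int) -> OccurrenceSet:
    """Uniform sample without replacement down to ``max_n`` records."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    n = len(occ)
    if n <= max_n:
        return occ
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=max_n, replace=False))
    return occ._with(occ.records.iloc[keep], subsample_seed=seed, subsample_max=max_n)


# ---------------------------------------------------------------------------
# Bioclim raster stacks
# ---------------------------------------------------------------------------

@dataclass
class BioclimStack:
    """The 19 co-registered bioclimatic rasters for one epoch/GCM.

    ``values`` has shape (19, n_rows, n_cols); ``mask`` is True on valid
    cells (the union of per-layer nodata masks is applied to all layers).
    """

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray
    epoch_label: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_BIOCLIM, self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"expected {N_BIOCLIM} layers of shape "
                f"({self.geometry.n_rows}, {self.geometry.n_cols}), got {v.shape}"
            )
        mask = np.asarray(self.mask, dtype=bool)
        v = v.copy()
        v[:, ~mask] = np.nan
        self.values = v
        self.mask = mask

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    def layer(self, i: int) -> np.ndarray:
        return self.values[i]

    def cell_values(self, rows, cols) -> np.ndarray:
        """Climate vectors at cells; shape (n_points, 19)."""
        return self.values[:, rows, cols].T

    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.mask)


def read_ascii_grid(path: str | Path) -> tuple[GridGeometry, np.ndarray]:
    """Read a single ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # center registration
        xll = header["xllcenter"] - cellsize / 2
        yll = header["yllcenter"] - cellsize / 2
    nodata = header.get("nodata_value", -9999.0)
    data = np.asarray(data, dtype=float).reshape(n_rows, n_cols)
    geom = GridGeometry(xll, yll, cellsize, n_rows, n_cols, nodata)
    data = np.where(data == nodata, np.nan, data)
    return geom, data


def write_ascii_grid(path: str | Path, geom: GridGeometry, data: np.ndarray) -> None:
    """Write one layer as an ESRI ASCII grid; NaN cells become nodata."""
    data = np.asarray(data, dtype=float)
    if data.shape != (geom.n_rows, geom.n_cols):
        raise ValueError("data shape does not match grid geometry")
    out = np.where(np.isnan(data), geom.nodata, data)
    with open(path, "w") as fh:
        fh.write(f"ncols {geom.n_cols}\n")
        fh.write(f"nrows {geom.n_rows}\n")
        fh.write(f"xllcorner {geom.xll:.10g}\n")
        fh.write(f"yllcorner {geom.yll:.10g}\n")
        fh.write(f"cellsize {geom.cellsize:.10g}\n")
        fh.write(f"NODATA_value {geom.nodata:.10g}\n")
        np.savetxt(fh, out, fmt="%.8g")


def read_stack(paths: Sequence[str | Path], epoch_label: str) -> BioclimStack:
    """Read 19 co-registered layers into one stack.

    Raises if the layer count is not 19 or any layer disagrees on geometry
    (the error names the offending file).  Per-layer nodata masks are
    unioned, so a cell missing in any layer is missing in all.
    """
    paths = list(paths)
    if len(paths) != N_BIOCLIM:
        raise ValueError(f"expected {N_BIOCLIM} layers, got {len(paths)}")
    geom, first = read_ascii_grid(paths[0])
    layers = [first]
    for p in paths[1:]:
        g, data = read_ascii_grid(p)
        if not geom.approx_equal(g):
            raise ValueError(f"layer geometry mismatch in {p}")
        layers.append(data)
    values = np.stack(layers)
    mask = ~np.any(np.isnan(values), axis=0)
    return BioclimStack(geom, values, mask, epoch_label)


def write_stack(stack: BioclimStack, directory: str | Path, prefix: str = "bio") -> list[Path]:
    """Write each layer as ``<prefix><i>.asc`` (i = 1..19); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(stack.n_layers):
        p = directory / f"{prefix}{i + 1}.asc"
        write_ascii_grid(p, stack.geometry, stack.values[i])
        paths.append(p)
    return paths
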