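"""Thresholding suitability into ranges and measuring distance to a site.

A continuous suitability map becomes a presence/absence range via a
threshold — by default the 10th-percentile training-presence threshold,
the largest cutoff at which at least 90% of the training presences remain
predicted present.  The species' predicted distance to the focal site is
then zero if the site's cell is predicted present, otherwise the
great-circle distance to the nearest present cell center; an empty
predicted range yields the NOT_COMPUTED sentinel ("NC" in published
checklists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import GridGeometry, haversine_km
from .maxent import SuitabilityMap
from .status import NOT_COMPUTED


@dataclass(frozen=True)
class ThresholdRule:
    """How to turn training suitabilities into a presence cutoff.

    ``percentile_training_presence`` (default, p = 0.10) takes the
    nearest-rank p-quantile of the training-presence suitabilities;
    ``fixed_value`` uses a constant cutoff regardless of the data.
    """

    kind: str = "percentile_training_presence"
    percentile: float = 0.10
    value: float | None = None

    def __post_init__(self):
        if self.kind not in ("percentile_training_presence", "fixed_value"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "percentile_training_presence" and not 0 < self.percentile < 1:
            raise ValueError("percentile must lie in (0, 1)")
        if self.kind == "fixed_value" and self.value is None:
            raise ValueError("fixed_value rule requires a value")


def resolve_threshold(training_suitabilities, rule: ThresholdRule) -> float:
    """Resolve the cutoff from training-presence suitabilities.

    Nearest-rank percentile: the k-th smallest value with k = ceil(p * n),
    which guarantees that at least ceil((1 - p) * n) training presences
    stay predicted present under a ">= threshold" rule.
    """
    if rule.kind == "fixed_value":
        return float(rule.value)
    vals = np.sort(np.asarray(list(training_suitabilities), dtype=float))
    if vals.size == 0:
        raise ValueError("cannot resolve a percentile threshold from no training values")
    k = math.ceil(rule.percentile * vals.size)
    return float(vals[max(k, 1) - 1])


@dataclass
class BinaryRangeMap:
    """Presence/absence raster: 1 present, 0 absent, nodata outside mask."""

    geometry: GridGeometry
    present: np.ndarray  # bool, meaningful only where mask is True
    mask: np.ndarray
    threshold: float
    species_id: str | None = None
    season: str | None = None
    epoch_label: str | None = None

    @property
    def n_present(self) -> int:
        return int((self.present & self.mask).sum())


def binarize(suit: SuitabilityMap, threshold: float) -> BinaryRangeMap:
    """Cell-wise comparison: suitability >= threshold is presence."""
    with np.errstate(invalid="ignore"):
        present = np.where(suit.mask, suit.values >= threshold, False)
    present &= np.isfinite(np.where(suit.mask, suit.values, np.nan))
    return BinaryRangeMap(
        suit.geometry, present.astype(bool), suit.mask.copy(), float(threshold),
        epoch_label=suit.epoch_label,
    )


def distance_to_site(range_map: BinaryRangeMap, site: tuple[float, float]) -> float:
    """Distance (km) from the focal site to the nearest predicted-present cell.

    Zero iff the site's own cell is present; :data:`NOT_COMPUTED` when the
    predicted range is empty.  The site must lie inside the grid extent.
    """
    lon, lat = site
    geom = range_map.geometry
    row, col = geom.cell_of(lon, lat)  # raises outside extent
    if range_map.mask[row, col] and range_map.present[row, col]:
        return 0.0
    rows, cols = np.nonzero(range_map.present & range_map.mask)
    if len(rows) == 0:
        return NOT_COMPUTED
    lons = geom.xll + (cols + 0.5) * geom.cellsize
    lats = geom.yll + (geom.n_rows - rows - 0.5) * geom.cellsize
    return float(haversine_km(lon, lat, lons, lats).min())


@dataclass
class SeasonEpochPrediction:
    """Distance-to-site record for one (species, season, epoch, GCM)."""

    species_id: str
    season: str
    epoch_label: str
    distance_km: float
    threshold: float
    n_present_cells: int

    @property
    def not_computed(self) -> bool:
        return not math.isfinite(self.distance_km)
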