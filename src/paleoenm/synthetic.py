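"""Synthetic two-epoch climates and species with known niches.

The generator emulates the inputs of the paleodistribution pipeline at
desk scale: a stack of 19 smooth climate surfaces at a "present" epoch, a
shifted stack standing in for an LGM reconstruction, and species whose
suitability is a known Gaussian product kernel of the climate.  Because
the true suitability is known everywhere, every downstream stage —
model fitting, thresholding, distance measurement, status classification —
can be tested against ground truth rather than against another model.

Suitability for a species with niche center mu and widths sigma is

    s(x) = prevalence * prod_j exp(-((e_j(x) - mu_j) / sigma_j)^2 / 2)

so log-suitability is exactly quadratic in the climate variables: a
maximum-entropy model with linear + quadratic features can represent the
truth, which is what makes parameter-recovery tests sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data_io import BREEDING, WINTER, BioclimStack, N_BIOCLIM, OccurrenceSet
from .geometry import GridGeometry, haversine_km
from .maxent import SuitabilityMap
from .range_mapping import ThresholdRule, binarize, distance_to_site
from .status import ResidencyStatus, classify_status


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerGradient:
    """Trend + noise parameters for one synthetic climate layer.

    value = base + ew_slope * (lon - lon_ref) + ns_slope * (lat - lat_ref)
            + noise_amp * smooth_noise
    """

    base: float
    ns_slope: float = 0.0
    ew_slope: float = 0.0
    noise_amp: float = 0.0
    noise_scale_cells: float = 3.0


def default_gradients() -> list[LayerGradient]:
    """Mildly bioclim-flavored defaults: 11 temperature-like layers (deg C,
    cooling northward) and 8 precipitation-like layers (mm, wetting
    northward), each with smooth spatial noise.

    The deterministic gradients deliberately differ from layer to layer
    (varying north-south and east-west slopes), so the layers jointly span
    a two-dimensional signal subspace rather than replicating one shared
    trend.  That matters for identifiability: when every layer carries the
    same signal, a fitted model can express a niche through static noise
    contrasts between layers, and those contrasts do not move when the
    climate bands are displaced to another epoch.  With diverse gradients
    the climate vector identifies location, and an epoch displacement acts
    coherently on everything a model can learn.  Noise amplitudes are kept
    small relative to the signal for the same reason.
    """
    grads = []
    for j in range(11):
        ns = -0.8 - 0.05 * (j - 5)  # -0.55 .. -1.05 deg C per degree lat
        ew = 0.15 + 0.08 * (j - 5)  # -0.25 .. +0.63 per degree lon
        grads.append(LayerGradient(base=15.0 + j, ns_slope=ns, ew_slope=ew, noise_amp=0.4))
    for j in range(8):
        ns = 25.0 + 2.0 * (j - 3.5)  # 18 .. 32 mm per degree lat
        ew = -5.0 + 2.5 * (j - 3.5)  # -13.75 .. +6.25 per degree lon
        grads.append(LayerGradient(base=600.0 + 40 * j, ns_slope=ns, ew_slope=ew, noise_amp=15.0))
    return grads


def make_climate(
    grid: GridGeometry,
    gradients: list[LayerGradient] | None = None,
    seed: int = 0,
    epoch_label: str = "present",
    mask: np.ndarray | None = None,
) -> BioclimStack:
    """Generate 19 smooth, spatially autocorrelated climate layers.

    Noise is white noise smoothed with a Gaussian filter (sigma =
    ``noise_scale_cells``) and rescaled to unit standard deviation before
    applying ``noise_amp``; deterministic per seed.
    """
    if gradients is None:
        gradients = default_gradients()
    if len(gradients) != N_BIOCLIM:
        raise ValueError(f"expected {N_BIOCLIM} layer gradients")
    rng = np.random.default_rng(seed)
    lon, lat = grid.meshgrid()
    lon_ref, lat_ref = lon.mean(), lat.mean()
    layers = []
    for g in gradients:
        vals = g.base + g.ew_slope * (lon - lon_ref) + g.ns_slope * (lat - lat_ref)
        if g.noise_amp > 0:
            noise = gaussian_filter(rng.standard_normal(lon.shape), g.noise_scale_cells)
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
            vals = vals + g.noise_amp * noise
        layers.append(vals)
    values = np.stack(layers)
    if mask is None:
        mask = np.ones(lon.shape, dtype=bool)
    return BioclimStack(grid, values, mask, epoch_label)


@dataclass(frozen=True)
class EpochShift:
    """Per-layer climate change between epochs.

    new = scale * old + offset + ns_gradient * (lat - lat_ref).  A zero
    shift (offsets 0, scales 1, gradients 0) returns an identical stack.
    """

    offsets: np.ndarray = field(default_factory=lambda: np.zeros(N_BIOCLIM))
    scales: np.ndarray = field(default_factory=lambda: np.ones(N_BIOCLIM))
    ns_gradients: np.ndarray = field(default_factory=lambda: np.zeros(N_BIOCLIM))


def lgm_default_shift(
    gradients: list[LayerGradient] | None = None,
    displacement_deg: float = 5.0,
) -> EpochShift:
    """Stylized glacial contrast: a uniform equatorward displacement of the
    climate surfaces.

    Every cell takes on the climate currently found ``displacement_deg``
    degrees of latitude to its north, so each layer's offset is its own
    north-south slope times the displacement (with the default gradients,
    roughly -3 to -5 deg C on the temperature-like layers and +90 to
    +160 mm on the precipitation-like layers).  Displacing all layers
    coherently keeps the glacial climate combinations inside the realized
    (present-day) climate space, which is the regime where niche
    projections between epochs are well defined.
    """
    if gradients is None:
        gradients = default_gradients()
    offsets = np.array([g.ns_slope * displacement_deg for g in gradients])
    return EpochShift(offsets)


def apply_epoch_shift(stack: BioclimStack, shift: EpochShift, epoch_label: str = "LGM") -> BioclimStack:
    """Apply a per-layer affine climate shift; geometry and mask unchanged."""
    _, lat = stack.geometry.meshgrid()
    lat_ref = lat.mean()
    values = (
        np.asarray(shift.scales)[:, None, None] * stack.values
        + np.asarray(shift.offsets)[:, None, None]
        + np.asarray(shift.ns_gradients)[:, None, None] * (lat - lat_ref)[None]
    )
    return BioclimStack(stack.geometry, values, stack.mask.copy(), epoch_label)


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """A species with a known Gaussian climatic niche.

    ``niche_center`` and ``niche_width`` are 19-vectors in the native units
    of each climate layer; the winter niche center is
    ``niche_center + seasonal_offset``.  ``max_prevalence`` scales the peak
    suitability.
    """

    species_id: str
    niche_center: np.ndarray
    niche_width: np.ndarray
    seasonal_offset: np.ndarray = field(default_factory=lambda: np.zeros(N_BIOCLIM))
    max_prevalence: float = 1.0

    def __post_init__(self):
        if not 0 < self.max_prevalence <= 1:
            raise ValueError("max_prevalence must lie in (0, 1]")
        if np.any(np.asarray(self.niche_width) <= 0):
            raise ValueError("niche widths must be strictly positive")

    def center_for(self, season: str) -> np.ndarray:
        c = np.asarray(self.niche_center, dtype=float)
        if season == WINTER:
            return c + np.asarray(self.seasonal_offset, dtype=float)
        if season != BREEDING:
            raise ValueError(f"unknown season {season!r}")
        return c


def true_suitability(spec: SyntheticSpeciesSpec, stack: BioclimStack, season: str = BREEDING) -> SuitabilityMap:
    """Ground-truth suitability map: Gaussian product kernel over layers."""
    mu = spec.center_for(season)
    sigma = np.asarray(spec.niche_width, dtype=float)
    z = (stack.values - mu[:, None, None]) / sigma[:, None, None]
    log_s = -0.5 * np.sum(z**2, axis=0)
    values = spec.max_prevalence * np.exp(log_s)
    values[~stack.mask] = np.nan
    return SuitabilityMap(stack.geometry, values, stack.mask.copy(), scale="truth", epoch_label=stack.epoch_label)


def sample_presences(
    spec: SyntheticSpeciesSpec,
    stack: BioclimStack,
    season: str,
    n: int,
    seed: int,
) -> OccurrenceSet:
    """Draw ``n`` presence points with probability proportional to suitability.

    Draws are multinomial over cells and land on cell centers (no
    within-cell jitter).  The returned occurrence set holds the distinct
    sampled cells (duplicate coordinates are collapsed on ingestion, the
    same convention the model fit applies); the full per-cell draw counts
    are kept in ``attrs['cell_counts']`` so empirical density can be
    compared against suitability.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    s = true_suitability(spec, stack, season)
    probs = np.where(stack.mask, s.values, 0.0).ravel()
    probs = np.nan_to_num(probs, nan=0.0)
    total = probs.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    probs = probs / total
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs).reshape(stack.mask.shape)
    rows, cols = np.nonzero(counts)
    lons = stack.geometry.xll + (cols + 0.5) * stack.geometry.cellsize
    lats = stack.geometry.yll + (stack.geometry.n_rows - rows - 0.5) * stack.geometry.cellsize
    df = pd.DataFrame({"lon": lons, "lat": lats, "source": "synthetic"})
    occ = OccurrenceSet(spec.species_id, season, df)
    occ.attrs["cell_counts"] = counts
    occ.attrs["n_draws"] = n
    return occ


def _weighted_nearest_rank(values: np.ndarray, weights: np.ndarray, p: float) -> float:
    """p-quantile of ``values`` under ``weights`` (nearest rank on the
    weighted CDF): the smallest v with W(v' <= v) >= p."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cdf = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cdf, p, side="left"))
    return float(v[min(idx, len(v) - 1)])


def true_threshold(suit: SuitabilityMap, rule: ThresholdRule, n_draws: int | None = None) -> float:
    """Expectation-level analogue of the training-presence threshold.

    The pipeline resolves its percentile threshold over the *distinct*
    presence cells (duplicate draws collapse to one record).  The
    expectation-level analogue therefore weights each cell by the
    probability that it receives at least one of ``n_draws`` multinomial
    draws, w_i = 1 - (1 - p_i)^n with p_i proportional to suitability, and
    takes the weighted nearest-rank quantile of the suitability values.
    With ``n_draws=None`` the per-draw (suitability-weighted) quantile is
    used instead — the analogue for data where every draw is kept.
    Deterministic; no sampling involved.
    """
    if rule.kind == "fixed_value":
        return float(rule.value)
    vals = suit.values[suit.mask]
    vals = vals[np.isfinite(vals)]
    if vals.sum() <= 0:
        raise ValueError("all-zero suitability")
    if n_draws is None:
        weights = vals
    else:
        p = vals / vals.sum()
        weights = 1.0 - (1.0 - p) ** n_draws
    return _weighted_nearest_rank(vals, weights, rule.percentile)


def true_status(
    spec: SyntheticSpeciesSpec,
    present_stack: BioclimStack,
    lgm_stack: BioclimStack,
    site: tuple[float, float],
    threshold_rule: ThresholdRule,
    D: float = 100.0,
    n_draws: int | None = None,
) -> tuple[ResidencyStatus, ResidencyStatus]:
    """Ground-truth residency status at (LGM, present).

    Uses the true (not fitted) suitability with the same rules as the main
    pipeline: per season, the threshold is resolved on the present
    (training) epoch and then applied unchanged to both epochs' maps,
    mirroring how a training-presence threshold is carried onto the LGM
    projection; distances and classification are identical to the fitted
    path.
    """
    dists: dict[tuple[str, str], float] = {}
    for season in (BREEDING, WINTER):
        train = true_suitability(spec, present_stack, season)
        if np.nansum(train.values) <= 0.0:
            # seasonal niche realized nowhere at the training epoch: no
            # training presences exist, so no range can be predicted
            for label in ("lgm", "present"):
                dists[(label, season)] = float("inf")
            continue
        thr = true_threshold(train, threshold_rule, n_draws)
        for label, stack in (("lgm", lgm_stack), ("present", present_stack)):
            s = true_suitability(spec, stack, season)
            dists[(label, season)] = distance_to_site(binarize(s, thr), site)
    lgm = classify_status(dists[("lgm", BREEDING)], dists[("lgm", WINTER)], D)
    present = classify_status(dists[("present", BREEDING)], dists[("present", WINTER)], D)
    return lgm, present


# ---------------------------------------------------------------------------
# Recovery battery
# ---------------------------------------------------------------------------

def default_battery_grid() -> GridGeometry:
    """Half-degree grid over a western-North-America-sized extent."""
    return GridGeometry(xll=-125.0, yll=28.0, cellsize=0.5, n_rows=40, n_cols=50)


def make_battery(
    n_species: int,
    present: BioclimStack,
    lgm: BioclimStack,
    site: tuple[float, float],
    threshold_rule: ThresholdRule,
    D: float = 100.0,
    seed: int = 0,
    n_draws: int | None = None,
    width_factor: float = 0.75,
    n_active_layers: int = 4,
    margin_band: tuple[float, float] = (0.5, 2.0),
    near_site_km: float = 120.0,
    max_tries: int = 200,
) -> list[tuple[SyntheticSpeciesSpec, ResidencyStatus, ResidencyStatus]]:
    """Generate species with well-separated niches plus their true statuses.

    Each species' niche center is the present-day climate at a seeded
    anchor cell.  Each species is limited by ``n_active_layers`` randomly
    chosen climate variables (widths ``width_factor`` times that layer's
    spatial standard deviation) and is broadly tolerant of the rest
    (widths 10x the spatial standard deviation) — mirroring how real
    species respond sharply to a few limiting factors.  Half
    the anchors are drawn from cells within ``near_site_km`` of the focal
    site so site-occupying and site-absent species both occur, and the
    winter niche is anchored at a second cell (possibly far away), making
    breeding-only / winter-only / resident / absent outcomes all reachable.
    A rejection rule enforces the "well-separated niches" condition: a
    candidate is kept only if its true statuses are decisive, i.e. (a) no
    season/epoch distance to the site falls inside the ambiguous band
    ``margin_band * D``, and (b) the true statuses are unchanged when the
    resolved threshold is halved or doubled.  Species failing either test
    sit so close to the classification boundary that their ground truth
    would flip under an infinitesimal perturbation of the suitability
    surface — there is nothing decisive for a fitted model to recover.
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(present.mask)
    geom = present.geometry
    cell_lons = geom.xll + (cols + 0.5) * geom.cellsize
    cell_lats = geom.yll + (geom.n_rows - rows - 0.5) * geom.cellsize
    near = np.flatnonzero(haversine_km(site[0], site[1], cell_lons, cell_lats) <= near_site_km)
    if near.size == 0:
        raise ValueError("no valid cells near the focal site")
    layer_sd = np.maximum(np.nanstd(present.values, axis=(1, 2)), 1e-6)
    out = []
    lo, hi = margin_band[0] * D, margin_band[1] * D
    for i in range(n_species):
        for _ in range(max_tries):
            active = rng.choice(N_BIOCLIM, size=n_active_layers, replace=False)
            widths = layer_sd * 10.0
            widths[active] = layer_sd[active] * width_factor
            a = rng.choice(near) if rng.random() < 0.5 else rng.integers(0, len(rows))
            b = rng.integers(0, len(rows))
            center = present.cell_values([rows[a]], [cols[a]])[0]
            # half the species winter where they breed; the rest elsewhere
            if rng.random() < 0.5:
                offset = np.zeros(N_BIOCLIM)
            else:
                offset = present.cell_values([rows[b]], [cols[b]])[0] - center
            spec = SyntheticSpeciesSpec(
                species_id=f"synthetic_{i:03d}",
                niche_center=center,
                niche_width=widths,
                seasonal_offset=offset,
            )
            # distances per (season, epoch) at the resolved threshold and at
            # its halved/doubled variants
            d = {}
            ok = True
            for season in (BREEDING, WINTER):
                train = true_suitability(spec, present, season)
                if np.nansum(train.values) <= 0.0:
                    for label in ("present", "lgm"):
                        for k in (0.5, 1.0, 2.0):
                            d[(season, label, k)] = float("inf")
                    continue
                thr = true_threshold(train, threshold_rule, n_draws)
                maps = {
                    label: true_suitability(spec, stack, season)
                    for label, stack in (("present", present), ("lgm", lgm))
                }
                for label, smap in maps.items():
                    for k in (0.5, 1.0, 2.0):
                        d[(season, label, k)] = distance_to_site(binarize(smap, k * thr), site)
                    if np.isfinite(d[(season, label, 1.0)]) and lo <= d[(season, label, 1.0)] <= hi:
                        ok = False
            if ok:
                statuses = {}
                for label in ("present", "lgm"):
                    per_k = {
                        k: classify_status(d[(BREEDING, label, k)], d[(WINTER, label, k)], D)
                        for k in (0.5, 1.0, 2.0)
                    }
                    if len(set(per_k.values())) > 1:
                        ok = False
                        break
                    statuses[label] = per_k[1.0]
            if ok:
                out.append((spec, statuses["lgm"], statuses["present"]))
                break
        else:
            raise RuntimeError("could not find a well-separated niche; widen margin_band")
    return out
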