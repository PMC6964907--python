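"""Synthetic climate and species generators against closed-form oracles."""

import numpy as np
import pytest

from paleoenm import synthetic
from paleoenm.data_io import BREEDING, N_BIOCLIM, WINTER
from paleoenm.geometry import GridGeometry, haversine_km
from paleoenm.range_mapping import ThresholdRule
from paleoenm.status import ResidencyStatus
from paleoenm.synthetic import (
    EpochShift,
    LayerGradient,
    SyntheticSpeciesSpec,
    apply_epoch_shift,
    make_climate,
    sample_presences,
    true_status,
    true_suitability,
)


@pytest.fixture
def grid():
    return GridGeometry(xll=-120.0, yll=30.0, cellsize=0.5, n_rows=12, n_cols=16)


# ---------------------------------------------------------------------------
# make_climate
# ---------------------------------------------------------------------------

def test_zero_noise_gradient_reproduces_the_plane(grid):
    grads = [LayerGradient(base=5.0 + j, ns_slope=2.0, ew_slope=-1.0) for j in range(N_BIOCLIM)]
    stack = make_climate(grid, grads, seed=0)
    lon, lat = grid.meshgrid()
    for j in (0, 7, 18):
        expected = (5.0 + j) + 2.0 * (lat - lat.mean()) - 1.0 * (lon - lon.mean())
        np.testing.assert_allclose(stack.values[j], expected, atol=1e-12)


def test_climate_determinism_per_seed(grid):
    a = make_climate(grid, seed=5)
    b = make_climate(grid, seed=5)
    c = make_climate(grid, seed=6)
    np.testing.assert_array_equal(a.values, b.values)
    assert not np.allclose(a.values, c.values)


# ---------------------------------------------------------------------------
# apply_epoch_shift
# ---------------------------------------------------------------------------

def test_zero_shift_is_identity(grid):
    stack = make_climate(grid, seed=1)
    shifted = apply_epoch_shift(stack, EpochShift())
    np.testing.assert_allclose(shifted.values, stack.values)


def test_additive_offset_moves_the_mean(grid):
    stack = make_climate(grid, seed=1)
    offsets = np.zeros(N_BIOCLIM)
    offsets[0] = 2.0
    shifted = apply_epoch_shift(stack, EpochShift(offsets=offsets))
    assert np.nanmean(shifted.values[0]) - np.nanmean(stack.values[0]) == pytest.approx(2.0)
    np.testing.assert_allclose(shifted.values[1], stack.values[1])


def test_scaling_quarters_the_variance(grid):
    stack = make_climate(grid, seed=1)
    scales = np.ones(N_BIOCLIM)
    scales[4] = 0.5
    shifted = apply_epoch_shift(stack, EpochShift(scales=scales))
    assert np.nanvar(shifted.values[4]) == pytest.approx(0.25 * np.nanvar(stack.values[4]))


# ---------------------------------------------------------------------------
# true_suitability
# ---------------------------------------------------------------------------

def test_suitability_peaks_at_niche_center(grid):
    stack = make_climate(grid, seed=2)
    center = stack.cell_values([4], [7])[0]
    spec = SyntheticSpeciesSpec("sp", center, np.full(N_BIOCLIM, 1.0), max_prevalence=0.8)
    s = true_suitability(spec, stack, BREEDING)
    assert s.values[4, 7] == pytest.approx(0.8)
    assert np.nanmax(s.values) == pytest.approx(0.8)


def test_infinite_widths_give_uniform_suitability(grid):
    stack = make_climate(grid, seed=2)
    spec = SyntheticSpeciesSpec("sp", stack.cell_values([0], [0])[0], np.full(N_BIOCLIM, 1e12))
    s = true_suitability(spec, stack, BREEDING)
    np.testing.assert_allclose(s.values[stack.mask], 1.0, rtol=1e-6)


def test_hand_computed_gaussian_kernel(grid):
    """Two informative layers, everything else flat: s = exp(-(z1^2+z2^2)/2)."""
    stack = make_climate(grid, seed=3)
    center = stack.cell_values([5], [5])[0].copy()
    widths = np.full(N_BIOCLIM, 1e12)
    widths[0], widths[1] = 2.0, 3.0
    spec = SyntheticSpeciesSpec("sp", center, widths)
    s = true_suitability(spec, stack, BREEDING)
    v = stack.cell_values([8], [11])[0]
    z = ((v[0] - center[0]) / 2.0, (v[1] - center[1]) / 3.0)
    assert s.values[8, 11] == pytest.approx(np.exp(-0.5 * (z[0] ** 2 + z[1] ** 2)), rel=1e-6)


def test_winter_center_is_offset(grid):
    stack = make_climate(grid, seed=3)
    center = stack.cell_values([5], [5])[0]
    offset = stack.cell_values([9], [2])[0] - center
    spec = SyntheticSpeciesSpec("sp", center, np.full(N_BIOCLIM, 1.0), seasonal_offset=offset)
    sw = true_suitability(spec, stack, WINTER)
    assert sw.values[9, 2] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# sample_presences
# ---------------------------------------------------------------------------

def test_concentrated_suitability_puts_all_points_in_one_cell(grid):
    stack = make_climate(grid, seed=4)
    center = stack.cell_values([6], [9])[0]
    spec = SyntheticSpeciesSpec("sp", center, np.full(N_BIOCLIM, 1e-3))
    occ = sample_presences(spec, stack, BREEDING, 50, seed=0)
    assert len(occ) == 1
    assert occ.attrs["cell_counts"][6, 9] == 50
    lon, lat = grid.center_of(6, 9)
    assert occ.lons[0] == pytest.approx(lon) and occ.lats[0] == pytest.approx(lat)


def test_uniform_suitability_sampling_is_multinomial_uniform():
    grid = GridGeometry(0.0, 0.0, 1.0, 5, 5)
    grads = [LayerGradient(base=1.0) for _ in range(N_BIOCLIM)]
    stack = make_climate(grid, grads, seed=0)
    spec = SyntheticSpeciesSpec("sp", np.ones(N_BIOCLIM), np.full(N_BIOCLIM, 1e12))
    n = 10_000
    occ = sample_presences(spec, stack, BREEDING, n, seed=1)
    counts = occ.attrs["cell_counts"].ravel()
    p = 1 / 25
    bound = 4 * np.sqrt(n * p * (1 - p))
    assert np.all(np.abs(counts - n * p) < bound)


def test_sample_presences_rejects_nonpositive_n(grid):
    stack = make_climate(grid, seed=4)
    spec = SyntheticSpeciesSpec("sp", stack.cell_values([0], [0])[0], np.ones(N_BIOCLIM))
    with pytest.raises(ValueError):
        sample_presences(spec, stack, BREEDING, 0, seed=0)


def test_sample_presences_determinism(grid):
    stack = make_climate(grid, seed=4)
    spec = SyntheticSpeciesSpec("sp", stack.cell_values([5], [5])[0], np.ones(N_BIOCLIM))
    a = sample_presences(spec, stack, BREEDING, 200, seed=9)
    b = sample_presences(spec, stack, BREEDING, 200, seed=9)
    np.testing.assert_array_equal(a.lons, b.lons)


# ---------------------------------------------------------------------------
# true_status
# ---------------------------------------------------------------------------

def _site_centered_spec(stack, site, widths_scale=1.0):
    row, col = stack.geometry.cell_of(*site)
    center = stack.cell_values([row], [col])[0]
    widths = np.maximum(np.nanstd(stack.values, axis=(1, 2)), 1e-6) * widths_scale
    return SyntheticSpeciesSpec("sp", center, widths)


def test_site_covering_niche_is_resident_at_both_epochs(grid):
    present = make_climate(grid, seed=5)
    lgm = apply_epoch_shift(present, EpochShift())  # unchanged climate
    site = grid.center_of(6, 8)
    spec = _site_centered_spec(present, site)
    rule = ThresholdRule()
    assert true_status(spec, present, lgm, site, rule) == (
        ResidencyStatus.RESIDENT,
        ResidencyStatus.RESIDENT,
    )


def test_winter_niche_off_grid_gives_breeding_only(grid):
    present = make_climate(grid, seed=5)
    lgm = apply_epoch_shift(present, EpochShift())
    site = grid.center_of(6, 8)
    spec = _site_centered_spec(present, site)
    far = SyntheticSpeciesSpec(
        "sp", spec.niche_center, spec.niche_width,
        seasonal_offset=np.full(N_BIOCLIM, 1e6),  # winter climate nowhere on grid
    )
    lgm_st, present_st = true_status(far, present, lgm, site, ThresholdRule())
    assert present_st == ResidencyStatus.BREEDING
    assert lgm_st == ResidencyStatus.BREEDING


def test_true_status_matches_per_cell_brute_force(grid):
    """Randomized specs against an independent per-cell re-implementation."""
    present = make_climate(grid, seed=6)
    lgm = apply_epoch_shift(present, synthetic.lgm_default_shift())
    site = grid.center_of(6, 8)
    rule = ThresholdRule()
    rng = np.random.default_rng(0)
    lon, lat = grid.meshgrid()

    def oracle_distance(spec, train_stack, stack, season):
        mu = spec.center_for(season)
        def smap(st):
            z = (st.values - mu[:, None, None]) / np.asarray(spec.niche_width)[:, None, None]
            return np.exp(-0.5 * (z**2).sum(axis=0))
        s_train, s = smap(train_stack), smap(stack)
        vals = np.sort(s_train.ravel())
        w = vals / vals.sum()
        thr = vals[np.searchsorted(np.cumsum(w), rule.percentile, side="left")]
        present_cells = s >= thr
        if not present_cells.any():
            return np.inf
        d = haversine_km(site[0], site[1], lon[present_cells], lat[present_cells])
        if present_cells[grid.cell_of(*site)]:
            return 0.0
        return d.min()

    for _ in range(5):
        r, c = rng.integers(0, grid.n_rows), rng.integers(0, grid.n_cols)
        widths = np.maximum(np.nanstd(present.values, axis=(1, 2)), 1e-6) * rng.uniform(0.5, 2.0)
        spec = SyntheticSpeciesSpec("sp", present.cell_values([r], [c])[0], widths)
        expected = []
        for stack in (lgm, present):
            b = oracle_distance(spec, present, stack, BREEDING)
            w = oracle_distance(spec, present, stack, WINTER)
            expected.append(
                ResidencyStatus.RESIDENT if (b <= 100 and w <= 100)
                else ResidencyStatus.BREEDING if b <= 100
                else ResidencyStatus.WINTER if w <= 100
                else ResidencyStatus.NOT_PRESENT
            )
        assert true_status(spec, present, lgm, site, rule) == tuple(expected)


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------

def test_species_spec_invariants():
    with pytest.raises(ValueError):
        SyntheticSpeciesSpec("sp", np.zeros(N_BIOCLIM), np.zeros(N_BIOCLIM))
    with pytest.raises(ValueError):
        SyntheticSpeciesSpec("sp", np.zeros(N_BIOCLIM), np.ones(N_BIOCLIM), max_prevalence=0.0)
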