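"""Maxent core: features, background, L1 coordinate descent, projection."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import spearmanr

from paleoenm import maxent, synthetic
from paleoenm.data_io import BREEDING, N_BIOCLIM
from paleoenm.geometry import AzimuthalEquidistant, GridGeometry
from paleoenm.maxent import (
    FeatureExpansion,
    auto_feature_classes,
    build_background,
    fit_maxent,
    full_extent_background,
    load_model,
    predict,
    save_model,
)


# ---------------------------------------------------------------------------
# feature expansion
# ---------------------------------------------------------------------------

@pytest.fixture
def bg_values():
    rng = np.random.default_rng(0)
    return rng.uniform([0, 10], [4, 30], size=(200, 2))


def test_linear_feature_is_zero_at_background_min(bg_values):
    exp = FeatureExpansion.fit(bg_values, ("linear",))
    at_min = exp.expand(bg_values.min(axis=0)[None, :])
    np.testing.assert_allclose(at_min, 0.0, atol=1e-12)


def test_quadratic_feature_is_one_at_background_max(bg_values):
    exp = FeatureExpansion.fit(bg_values, ("quadratic",))
    at_max = exp.expand(bg_values.max(axis=0)[None, :])
    np.testing.assert_allclose(at_max, 1.0, atol=1e-12)


def test_hinge_hand_computation():
    bg = np.linspace(0.0, 10.0, 101)[:, None]
    exp = FeatureExpansion.fit(bg, ("hinge",), n_hinge_knots=1)  # single knot at 5
    (feat,) = [f for f in exp.features]
    assert feat.knot == pytest.approx(5.0)
    vals = exp.expand(np.array([[3.0], [5.0], [7.5]]))
    np.testing.assert_allclose(vals.ravel(), [0.0, 0.0, 0.5], atol=1e-12)


def test_expand_rejects_wrong_vector_length(bg_values):
    exp = FeatureExpansion.fit(bg_values, ("linear",))
    with pytest.raises(ValueError):
        exp.expand(np.zeros((3, 5)))


def test_constant_variable_produces_no_feature():
    bg = np.column_stack([np.linspace(0, 1, 50), np.full(50, 7.0)])
    exp = FeatureExpansion.fit(bg, ("linear", "quadratic"))
    assert all(f.vars == (0,) for f in exp.features)


def test_auto_feature_ladder():
    assert auto_feature_classes(5) == ("linear",)
    assert auto_feature_classes(12) == ("linear", "quadratic")
    assert auto_feature_classes(40) == ("linear", "quadratic", "hinge")
    assert "product" in auto_feature_classes(200)


# ---------------------------------------------------------------------------
# background construction
# ---------------------------------------------------------------------------

def _ray_casting_contains(poly_xy, px, py):
    """Independent point-in-polygon oracle (even-odd rule)."""
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def test_background_subset_of_square_hull(occ_factory):
    # small extent so projection distortion stays below the 1 mm tolerance
    grid = GridGeometry(0.0, 0.0, 0.001, 10, 10)
    stack = synthetic.make_climate(grid, seed=0)
    # occurrences at the four corner cell centers
    occ = occ_factory([0.0005, 0.0095, 0.0005, 0.0095], [0.0005, 0.0005, 0.0095, 0.0095])
    bg = build_background(occ, stack, buffer_km=0.0, n_bg=50, seed=0)
    assert not bg.used_bbox_fallback
    assert bg.n_background == 50
    assert len(bg.eligible_rows) == 100  # hull covers every cell center


def test_background_hull_matches_ray_casting_oracle(occ_factory):
    grid = GridGeometry(0.0, 40.0, 0.2, 20, 20)
    stack = synthetic.make_climate(grid, seed=1)
    rng = np.random.default_rng(3)
    occ = occ_factory(rng.uniform(0.5, 3.5, 12), rng.uniform(40.5, 43.5, 12))
    bg = build_background(occ, stack, buffer_km=0.0, n_bg=10_000, seed=0)
    poly = np.asarray(bg.study_area.exterior.coords)[:-1]
    got = set(zip(bg.eligible_rows.tolist(), bg.eligible_cols.tolist()))
    expected = set()
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            lon, lat = grid.center_of(r, c)
            x, y = bg.projection.forward(lon, lat)
            if _ray_casting_contains(poly, float(x), float(y)):
                expected.add((r, c))
    # boundary cells may differ between covers- and strict-containment;
    # interior cells must agree exactly
    assert expected <= got
    assert len(got - expected) <= len(poly) * 4


def test_huge_buffer_makes_all_valid_cells_eligible(occ_factory):
    grid = GridGeometry(0.0, 0.0, 1.0, 10, 10)
    stack = synthetic.make_climate(grid, seed=0)
    occ = occ_factory([4.5, 5.5], [4.5, 5.5])
    bg = build_background(occ, stack, buffer_km=5000.0, n_bg=10_000, seed=0)
    assert len(bg.eligible_rows) == 100


def test_two_occurrences_fall_back_to_bbox(occ_factory):
    grid = GridGeometry(0.0, 0.0, 1.0, 10, 10)
    stack = synthetic.make_climate(grid, seed=0)
    occ = occ_factory([1.5, 7.5], [2.5, 2.5])  # hull degenerates to a segment
    bg = build_background(occ, stack, buffer_km=300.0, n_bg=20, seed=0)
    assert bg.used_bbox_fallback
    assert bg.n_background == 20


def test_fewer_cells_than_requested_warns_and_uses_all(occ_factory):
    grid = GridGeometry(0.0, 0.0, 1.0, 10, 10)
    stack = synthetic.make_climate(grid, seed=0)
    occ = occ_factory([4.5, 5.5], [4.5, 5.5])
    with pytest.warns(UserWarning, match="eligible cells"):
        bg = build_background(occ, stack, buffer_km=5000.0, n_bg=500, seed=0)
    assert bg.n_background == 100


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_no_signal_gives_zero_weight_and_uniform_output():
    bg = np.array([[0.0], [1.0]])
    pres = np.array([[0.0], [1.0]])  # presence mean equals background mean
    model = fit_maxent(pres, bg, betas=np.zeros(1))
    assert model.lambdas[0] == pytest.approx(0.0, abs=1e-6)
    q = np.exp(bg @ model.lambdas - model.log_partition)
    np.testing.assert_allclose(q, 0.5, atol=1e-6)


def test_single_feature_closed_form_matches_root_finding_oracle():
    """2-cell background, binary feature: unpenalized lambda solves
    presence-mean = E_q[f]; the oracle is an independent brentq solve."""
    bg = np.array([[0.0], [1.0]])
    pres = np.array([[1.0], [1.0], [0.0]])  # presence mean 2/3
    p_bar = 2 / 3
    oracle = brentq(lambda lam: np.exp(lam) / (1 + np.exp(lam)) - p_bar, -20, 20)
    model = fit_maxent(pres, bg, betas=np.zeros(1), tol=1e-10)
    assert model.lambdas[0] == pytest.approx(oracle, abs=1e-6)
    assert oracle == pytest.approx(np.log(2), abs=1e-12)


def test_huge_regularization_shrinks_all_weights_to_zero():
    rng = np.random.default_rng(0)
    bg = rng.uniform(size=(100, 4))
    pres = rng.uniform(0.5, 1.0, size=(30, 4))
    model = fit_maxent(pres, bg, reg_multiplier=1e6)
    np.testing.assert_allclose(model.lambdas, 0.0, atol=1e-12)


def test_objective_is_monotone_nondecreasing():
    rng = np.random.default_rng(1)
    bg = rng.uniform(size=(300, 6))
    pres = rng.uniform(0.3, 1.0, size=(50, 6))
    model = fit_maxent(pres, bg)
    path = np.asarray(model.objective_path)
    assert np.all(np.diff(path) >= -1e-10)


def test_kkt_soft_feature_matching_bound():
    rng = np.random.default_rng(2)
    bg = rng.uniform(size=(400, 8))
    pres = np.clip(rng.normal(0.7, 0.15, size=(60, 8)), 0, 1)
    model = fit_maxent(pres, bg, tol=1e-7)
    assert model.converged
    gap = np.abs(model.presence_mean - model.background_expectation)
    assert np.all(gap <= model.betas + 1e-6)


def test_degenerate_feature_is_dropped_with_warning():
    bg = np.column_stack([np.linspace(0, 1, 50), np.full(50, 0.3)])
    pres = np.column_stack([np.full(10, 0.8), np.full(10, 0.3)])
    with pytest.warns(UserWarning, match="zero-variance"):
        model = fit_maxent(pres, bg)
    assert model.lambdas[1] == 0.0


def test_fit_requires_minimum_data():
    with pytest.raises(ValueError):
        fit_maxent(np.empty((0, 2)), np.ones((5, 2)))
    with pytest.raises(ValueError):
        fit_maxent(np.ones((3, 2)), np.ones((1, 2)))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@pytest.fixture
def fitted_setup():
    grid = GridGeometry(-120.0, 30.0, 0.5, 20, 25)
    stack = synthetic.make_climate(grid, seed=3)
    center = stack.cell_values([10], [12])[0]
    widths = np.maximum(np.nanstd(stack.values, axis=(1, 2)), 1e-6)
    spec = synthetic.SyntheticSpeciesSpec("sp", center, widths)
    occ = synthetic.sample_presences(spec, stack, BREEDING, 400, seed=5)
    rows, cols, pres_values, _ = maxent.extract_presence_cells(occ, stack)
    bg = full_extent_background(stack, 500, seed=0)
    exp = FeatureExpansion.fit(bg.values, ("linear", "quadratic"))
    model = fit_maxent(
        exp.expand(pres_values, clamp=True), exp.expand(bg.values), feature_kinds=exp.kinds
    )
    return grid, stack, spec, bg, exp, model


def test_raw_output_sums_to_one_over_training_background(fitted_setup):
    _, stack, _, bg, exp, model = fitted_setup
    raw = predict(model, exp, stack, scale="raw")
    assert np.nansum(raw.values[bg.rows, bg.cols]) == pytest.approx(1.0, abs=1e-9)


def test_all_zero_model_predicts_uniform_raw_map(fitted_setup):
    _, stack, _, bg, exp, model = fitted_setup
    import dataclasses

    flat = dataclasses.replace(model, lambdas=np.zeros_like(model.lambdas), log_partition=np.log(bg.n_background))
    raw = predict(flat, exp, stack, scale="raw")
    vals = raw.values[stack.mask]
    np.testing.assert_allclose(vals, vals[0])


def test_fitted_suitability_rank_correlates_with_truth(fitted_setup):
    _, stack, spec, _, exp, model = fitted_setup
    fit_map = predict(model, exp, stack, scale="raw")
    true_map = synthetic.true_suitability(spec, stack, BREEDING)
    rho = spearmanr(fit_map.values[stack.mask], true_map.values[stack.mask]).statistic
    assert rho >= 0.9


def test_clamp_on_vs_off_differ_only_at_out_of_range_cells(fitted_setup):
    grid, stack, _, _, exp, model = fitted_setup
    shifted = stack.values.copy()
    shifted[0, 3, 3] = exp.var_max[0] + 50.0  # push one cell out of range
    from paleoenm.data_io import BioclimStack

    target = BioclimStack(grid, shifted, stack.mask.copy(), "proj")
    clamped = predict(model, exp, target, clamp=True, scale="raw")
    unclamped = predict(model, exp, target, clamp=False, scale="raw")
    diff = ~np.isclose(clamped.values, unclamped.values, equal_nan=True)
    assert diff[3, 3]
    assert diff.sum() == 1


def test_no_extrapolation_masks_out_of_range_cells(fitted_setup):
    grid, stack, _, _, exp, model = fitted_setup
    shifted = stack.values.copy()
    shifted[0, 3, 3] = exp.var_max[0] + 50.0
    from paleoenm.data_io import BioclimStack

    target = BioclimStack(grid, shifted, stack.mask.copy(), "proj")
    out = predict(model, exp, target, extrapolate=False, scale="cloglog")
    assert not out.mask[3, 3]
    assert np.isnan(out.values[3, 3])


def test_cloglog_values_bounded(fitted_setup):
    _, stack, _, _, exp, model = fitted_setup
    cll = predict(model, exp, stack, scale="cloglog")
    vals = cll.values[stack.mask]
    assert np.all((vals >= 0) & (vals <= 1))


def test_model_round_trip_through_text_files(tmp_path, fitted_setup):
    _, stack, _, _, exp, model = fitted_setup
    path = tmp_path / "model.lambdas"
    save_model(model, exp, path)
    model2, exp2 = load_model(path)
    a = predict(model, exp, stack, scale="cloglog")
    b = predict(model2, exp2, stack, scale="cloglog")
    np.testing.assert_allclose(b.values, a.values, equal_nan=True, rtol=1e-12)


def test_aeqd_distance_from_center_is_exact():
    proj = AzimuthalEquidistant(-115.0, 40.0)
    x, y = proj.forward(-113.0, 42.0)
    from paleoenm.geometry import haversine_km

    assert np.hypot(x, y) == pytest.approx(haversine_km(-115.0, 40.0, -113.0, 42.0), rel=1e-9)
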