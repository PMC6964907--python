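"""A from-scratch presence-background maximum-entropy niche model.

The model is the classic Maxent formulation: over a background sample of
available environments, fit the Gibbs distribution

    q(x) proportional to exp( sum_j lambda_j f_j(x) )

whose feature expectations match the presence sample's feature means as
closely as an L1 penalty allows.  Features f_j are derived from the
climate variables (linear, quadratic, product, hinge, threshold classes),
each scaled to [0, 1] over the background.  Fitting maximizes the
L1-penalized log-likelihood

    J(lambda) = mean_presence[ lambda . f ] - log Z(lambda)
                - sum_j beta_j |lambda_j|

by cyclic coordinate descent with soft-thresholding and a backtracking
line search, so J is non-decreasing at every accepted step.  At the
optimum the KKT conditions give the familiar soft feature-matching bound
|E_presence f_j - E_q f_j| <= beta_j.

Outputs: the raw scale is q normalized over the training background (sums
to 1 there); the cloglog scale is 1 - exp(-e^H q(x)) with H the entropy of
the fitted background distribution, the bounded suitability commonly used
for thresholding.  Projection onto another epoch's climate supports
clamping (truncate covariates to the training range) or, with
extrapolation disabled, masking out-of-range cells entirely.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from shapely import MultiPoint, Point, Polygon, box, contains_xy

from .data_io import BioclimStack, OccurrenceSet
from .geometry import AzimuthalEquidistant, GridGeometry

LINEAR = "linear"
QUADRATIC = "quadratic"
PRODUCT = "product"
HINGE = "hinge"
THRESHOLD = "threshold"

FEATURE_CLASSES = (LINEAR, QUADRATIC, PRODUCT, HINGE, THRESHOLD)

#: Default per-class regularization, interpolated on the presence count
#: (the published Maxent default tables, linear in sample size).
_BETA_TABLES = {
    LINEAR: ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    QUADRATIC: ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    PRODUCT: ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    HINGE: ([0, 1], [0.5, 0.5]),
    THRESHOLD: ([0, 100], [2.0, 1.0]),
}


def auto_feature_classes(n_presences: int) -> tuple[str, ...]:
    """Maxent's default feature-class ladder by presence count."""
    if n_presences < 10:
        return (LINEAR,)
    if n_presences < 15:
        return (LINEAR, QUADRATIC)
    if n_presences < 80:
        return (LINEAR, QUADRATIC, HINGE)
    return (LINEAR, QUADRATIC, HINGE, PRODUCT)


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    kind: str
    vars: tuple[int, ...]
    knot: float | None = None


@dataclass
class FeatureExpansion:
    """Feature definitions plus background normalization constants.

    A pure function of the climate values once fitted: every feature is
    scaled to [0, 1] over the background sample.  Hinge features use knots
    evenly spaced over each variable's background range.
    """

    var_min: np.ndarray
    var_max: np.ndarray
    features: list[FeatureDef]
    feat_min: np.ndarray
    feat_max: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def kinds(self) -> list[str]:
        return [f.kind for f in self.features]

    @classmethod
    def fit(
        cls,
        background_values: np.ndarray,
        classes: Sequence[str] = (LINEAR, QUADRATIC),
        n_hinge_knots: int = 50,
        n_threshold_knots: int = 10,
    ) -> "FeatureExpansion":
        """Define features and their [0, 1] scaling from background climate."""
        bg = np.asarray(background_values, dtype=float)
        if bg.ndim != 2:
            raise ValueError("background_values must be 2-D (points x variables)")
        n_vars = bg.shape[1]
        unknown = set(classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        vmin, vmax = bg.min(axis=0), bg.max(axis=0)
        defs: list[FeatureDef] = []
        for j in range(n_vars):
            if vmax[j] <= vmin[j]:
                continue  # constant variable: no informative feature
            if LINEAR in classes:
                defs.append(FeatureDef(LINEAR, (j,)))
            if QUADRATIC in classes:
                defs.append(FeatureDef(QUADRATIC, (j,)))
            if HINGE in classes:
                knots = np.linspace(vmin[j], vmax[j], n_hinge_knots + 2)[1:-1]
                defs.extend(FeatureDef(HINGE, (j,), float(k)) for k in knots)
            if THRESHOLD in classes:
                knots = np.linspace(vmin[j], vmax[j], n_threshold_knots + 2)[1:-1]
                defs.extend(FeatureDef(THRESHOLD, (j,), float(k)) for k in knots)
        if PRODUCT in classes:
            for i in range(n_vars):
                for j in range(i + 1, n_vars):
                    if vmax[i] > vmin[i] and vmax[j] > vmin[j]:
                        defs.append(FeatureDef(PRODUCT, (i, j)))
        exp = cls(vmin, vmax, defs, np.zeros(len(defs)), np.ones(len(defs)))
        raw = exp._raw(bg)
        fmin, fmax = raw.min(axis=0), raw.max(axis=0)
        keep = fmax - fmin > 1e-12
        if not np.all(keep):
            warnings.warn(f"dropping {int((~keep).sum())} degenerate (constant) features")
        exp.features = [d for d, k in zip(defs, keep) if k]
        exp.feat_min = fmin[keep]
        exp.feat_max = fmax[keep]
        return exp

    def _raw(self, values: np.ndarray) -> np.ndarray:
        """Unscaled feature values (hinge/threshold are already in [0, 1])."""
        cols = []
        for f in self.features:
            if f.kind == LINEAR:
                cols.append(values[:, f.vars[0]])
            elif f.kind == QUADRATIC:
                cols.append(values[:, f.vars[0]] ** 2)
            elif f.kind == PRODUCT:
                cols.append(values[:, f.vars[0]] * values[:, f.vars[1]])
            elif f.kind == HINGE:
                j = f.vars[0]
                span = self.var_max[j] - f.knot
                cols.append(np.clip((values[:, j] - f.knot) / span, 0.0, 1.0))
            elif f.kind == THRESHOLD:
                cols.append((values[:, f.vars[0]] > f.knot).astype(float))
            else:  # pragma: no cover
                raise ValueError(f.kind)
        return np.column_stack(cols) if cols else np.empty((len(values), 0))

    def in_training_range(self, values: np.ndarray) -> np.ndarray:
        """Boolean per point: all variables within the background range."""
        values = np.asarray(values, dtype=float)
        return np.all((values >= self.var_min) & (values <= self.var_max), axis=1)

    def expand(self, values: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Feature matrix for climate vectors; optionally clamp to the
        training range first.  Scaled features are clipped to [0, 1] when
        clamping so projections never leave the fitted response surface."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != len(self.var_min):
            raise ValueError(
                f"expected {len(self.var_min)} variables, got {values.shape[1]}"
            )
        if clamp:
            values = np.clip(values, self.var_min, self.var_max)
        raw = self._raw(values)
        scaled = (raw - self.feat_min) / (self.feat_max - self.feat_min)
        if clamp:
            scaled = np.clip(scaled, 0.0, 1.0)
        return scaled


def expand_features(values: np.ndarray, expansion: FeatureExpansion, clamp: bool = False) -> np.ndarray:
    """Functional alias for :meth:`FeatureExpansion.expand`."""
    return expansion.expand(values, clamp=clamp)


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSample:
    """Background cells drawn from the accessible study area.

    The study area is the minimum convex polygon of the occurrence records
    buffered by ``buffer_km``, constructed in a local azimuthal-equidistant
    projection (km units) about the record centroid.
    """

    study_area: Polygon
    projection: AzimuthalEquidistant
    rows: np.ndarray
    cols: np.ndarray
    lonlat: np.ndarray
    values: np.ndarray
    eligible_rows: np.ndarray
    eligible_cols: np.ndarray
    used_bbox_fallback: bool = False

    @property
    def n_background(self) -> int:
        return len(self.rows)


def _eligible_cells(stack: BioclimStack, polygon: Polygon, proj: AzimuthalEquidistant):
    rows, cols = stack.valid_cells()
    geom = stack.geometry
    lons = geom.xll + (cols + 0.5) * geom.cellsize
    lats = geom.yll + (geom.n_rows - rows - 0.5) * geom.cellsize
    x, y = proj.forward(lons, lats)
    # covers semantics with a 1 mm tolerance: cell centers sitting exactly on
    # the study-area boundary (e.g. hull vertices) count as inside
    inside = contains_xy(polygon.buffer(1e-6), x, y)
    return rows[inside], cols[inside]


def build_background(
    occ: OccurrenceSet,
    stack: BioclimStack,
    buffer_km: float = 150.0,
    n_bg: int = 10_000,
    seed: int = 0,
) -> BackgroundSample:
    """Sample background cells inside the buffered convex hull of the records.

    Falls back to a buffered bounding box when the records are fewer than
    three or collinear (reported via ``used_bbox_fallback``).  If fewer
    eligible cells exist than ``n_bg``, all are used with a warning.
    """
    if len(occ) == 0:
        raise ValueError("cannot build a background from zero occurrences")
    proj = AzimuthalEquidistant(float(np.mean(occ.lons)), float(np.mean(occ.lats)))
    x, y = proj.forward(occ.lons, occ.lats)
    hull = MultiPoint(list(zip(x, y))).convex_hull
    fallback = not isinstance(hull, Polygon)
    if fallback:
        minx, miny, maxx, maxy = hull.bounds if not isinstance(hull, Point) else (
            hull.x, hull.y, hull.x, hull.y
        )
        hull = box(minx, miny, maxx, maxy)
    study_area = hull.buffer(buffer_km) if buffer_km > 0 else hull
    el_rows, el_cols = _eligible_cells(stack, study_area, proj)
    if len(el_rows) == 0:
        raise ValueError("study area contains no valid climate cells")
    rng = np.random.default_rng(seed)
    if len(el_rows) <= n_bg:
        if len(el_rows) < n_bg:
            warnings.warn(
                f"only {len(el_rows)} eligible cells for {n_bg} requested background points; using all"
            )
        idx = np.arange(len(el_rows))
    else:
        idx = np.sort(rng.choice(len(el_rows), size=n_bg, replace=False))
    rows, cols = el_rows[idx], el_cols[idx]
    geom = stack.geometry
    lonlat = np.column_stack(
        [geom.xll + (cols + 0.5) * geom.cellsize,
         geom.yll + (geom.n_rows - rows - 0.5) * geom.cellsize]
    )
    return BackgroundSample(
        study_area=study_area,
        projection=proj,
        rows=rows,
        cols=cols,
        lonlat=lonlat,
        values=stack.cell_values(rows, cols),
        eligible_rows=el_rows,
        eligible_cols=el_cols,
        used_bbox_fallback=fallback,
    )


def full_extent_background(stack: BioclimStack, n_bg: int = 10_000, seed: int = 0) -> BackgroundSample:
    """Background drawn from every valid cell of the layer extent."""
    rows, cols = stack.valid_cells()
    geom = stack.geometry
    rng = np.random.default_rng(seed)
    if len(rows) > n_bg:
        idx = np.sort(rng.choice(len(rows), size=n_bg, replace=False))
        rows, cols = rows[idx], cols[idx]
    proj = AzimuthalEquidistant(
        geom.xll + geom.n_cols * geom.cellsize / 2, geom.yll + geom.n_rows * geom.cellsize / 2
    )
    lons = geom.xll + (cols + 0.5) * geom.cellsize
    lats = geom.yll + (geom.n_rows - rows - 0.5) * geom.cellsize
    x, y = proj.forward(lons, lats)
    hull = MultiPoint(list(zip(x, y))).convex_hull
    if not isinstance(hull, Polygon):
        hull = hull.buffer(1.0)
    return BackgroundSample(
        study_area=hull,
        projection=proj,
        rows=rows,
        cols=cols,
        lonlat=np.column_stack([lons, lats]),
        values=stack.cell_values(rows, cols),
        eligible_rows=rows,
        eligible_cols=cols,
    )


def extract_presence_cells(occ: OccurrenceSet, stack: BioclimStack):
    """Map occurrences to grid cells: drop off-grid and nodata points,
    collapse duplicate cells (Maxent convention).  Returns
    (rows, cols, climate values, report dict)."""
    geom = stack.geometry
    lons, lats = occ.lons, occ.lats
    inside = (
        (lons >= geom.xll) & (lons < geom.x_max) & (lats >= geom.yll) & (lats < geom.y_max)
    )
    rows, cols = geom.cells_of(lons[inside], lats[inside])
    on_data = stack.mask[rows, cols]
    rows, cols = rows[on_data], cols[on_data]
    cells = np.unique(np.column_stack([rows, cols]), axis=0)
    report = {
        "n_records": len(occ),
        "n_off_grid": int((~inside).sum()),
        "n_on_nodata": int((~on_data).sum()),
        "n_cells": len(cells),
    }
    if len(cells) == 0:
        raise ValueError("no presence records fall on valid climate cells")
    return cells[:, 0], cells[:, 1], stack.cell_values(cells[:, 0], cells[:, 1]), report


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    """Fitted weights plus the normalization constants needed to project.

    ``log_partition`` is log sum(exp(eta)) over the training background, so
    raw output exp(eta - log_partition) sums to 1 there; ``entropy`` is the
    entropy of the fitted background distribution, used by the cloglog
    transform.
    """

    lambdas: np.ndarray
    betas: np.ndarray
    reg_multiplier: float
    log_partition: float
    entropy: float
    n_presences: int
    n_background: int
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)
    presence_mean: np.ndarray | None = None
    background_expectation: np.ndarray | None = None
    feature_kinds: list[str] | None = None


def default_betas(
    n_presences: int,
    presence_features: np.ndarray,
    feature_kinds: Sequence[str],
    reg_multiplier: float = 1.0,
) -> np.ndarray:
    """Per-feature L1 penalties from the default per-class tables.

    beta_j = multiplier * beta_class(m) * s_j / sqrt(m), with s_j the
    presence-sample standard deviation of feature j (floored to avoid a
    vanishing penalty on presence-constant features).
    """
    m = max(n_presences, 1)
    s = presence_features.std(axis=0)
    s = np.maximum(s, 1e-2)
    beta = np.empty(len(feature_kinds))
    for j, kind in enumerate(feature_kinds):
        xs, ys = _BETA_TABLES.get(kind, _BETA_TABLES[LINEAR])
        beta[j] = np.interp(m, xs, ys) * s[j] / np.sqrt(m)
    return reg_multiplier * beta


def fit_maxent(
    presences: np.ndarray,
    background: np.ndarray,
    reg_multiplier: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-5,
    feature_kinds: Sequence[str] | None = None,
    betas: np.ndarray | None = None,
) -> MaxentModel:
    """Fit the L1-penalized maxent model by cyclic coordinate descent.

    ``presences`` and ``background`` are feature matrices from the same
    :class:`FeatureExpansion`.  One iteration is a full cycle over the
    features; each coordinate takes a soft-thresholded Newton step with
    backtracking, so the penalized objective never decreases.  The model
    is flagged converged when the KKT optimality violation drops to
    ``tol`` or below.
    """
    P = np.atleast_2d(np.asarray(presences, dtype=float))
    B = np.atleast_2d(np.asarray(background, dtype=float))
    if P.shape[0] < 1 or B.shape[0] < 2:
        raise ValueError("need at least 1 presence and 2 background points")
    if P.shape[1] != B.shape[1]:
        raise ValueError("presence and background feature dimensions differ")
    m, k = P.shape
    n = B.shape[0]
    kinds = list(feature_kinds) if feature_kinds is not None else [LINEAR] * k
    if len(kinds) != k:
        raise ValueError("feature_kinds length mismatch")
    if betas is None:
        betas = default_betas(m, P, kinds, reg_multiplier)
    betas = np.asarray(betas, dtype=float)

    p_mean = P.mean(axis=0)
    active = B.std(axis=0) > 1e-12
    if not np.all(active):
        warnings.warn(f"dropping {int((~active).sum())} zero-variance features from the fit")

    lam = np.zeros(k)
    eta = np.zeros(n)
    logZ = float(logsumexp(eta))

    def objective(lam_, logZ_):
        return float(p_mean @ lam_ - logZ_ - betas @ np.abs(lam_))

    obj = objective(lam, logZ)
    path = [obj]
    converged = False
    it = 0

    def sweep(indices):
        nonlocal obj, logZ, eta
        for j in indices:
            if not active[j]:
                continue
            fj = B[:, j]
            q = np.exp(eta - logZ)
            e = float(q @ fj)
            g = p_mean[j] - e
            h = float(q @ (fj * fj)) - e * e
            if h < 1e-12:
                continue
            z = lam[j] + g / h
            t = betas[j] / h
            new = np.sign(z) * max(abs(z) - t, 0.0)
            delta = new - lam[j]
            if delta == 0.0:
                continue
            # backtracking: guarantee the penalized objective is non-decreasing
            for _ in range(30):
                cand = lam[j] + delta
                eta_c = eta + delta * fj
                logZ_c = float(logsumexp(eta_c))
                obj_c = obj + p_mean[j] * delta - (logZ_c - logZ) - betas[j] * (
                    abs(cand) - abs(lam[j])
                )
                if obj_c >= obj - 1e-12:
                    lam[j] = cand
                    eta = eta_c
                    logZ = logZ_c
                    obj = obj_c
                    break
                delta *= 0.5

    def kkt_violation():
        q = np.exp(eta - logZ)
        g = p_mean - q @ B
        viol = np.where(
            lam == 0.0, np.maximum(np.abs(g) - betas, 0.0), np.abs(g - betas * np.sign(lam))
        )
        viol[~active] = 0.0
        return float(viol.max(initial=0.0))

    def polish_active_set():
        """Sign-fixed smooth solve over the nonzero coordinates.

        Coordinate descent identifies the sparsity pattern quickly but
        tail-converges slowly on correlated features; with the signs
        fixed, the restricted problem is smooth and a bounded quasi-Newton
        solve finishes it in a handful of iterations.
        """
        nonlocal obj, logZ, eta
        idx = np.flatnonzero(lam != 0.0)
        if idx.size == 0:
            return
        signs = np.sign(lam[idx])
        Bs = B[:, idx]

        def neg_obj(w):
            eta_w = Bs @ w
            logZ_w = float(logsumexp(eta_w))
            val = p_mean[idx] @ w - logZ_w - betas[idx] @ (signs * w)
            q_w = np.exp(eta_w - logZ_w)
            grad = p_mean[idx] - q_w @ Bs - betas[idx] * signs
            return -val, -grad

        bounds = [(0.0, None) if s > 0 else (None, 0.0) for s in signs]
        res = minimize(neg_obj, lam[idx], jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-15, "gtol": tol * 1e-2})
        if -res.fun >= obj - 1e-12:  # accept only non-decreasing moves
            lam[idx] = res.x
            eta = B @ lam
            logZ = float(logsumexp(eta))
            obj = objective(lam, logZ)

    all_idx = list(range(k))
    for it in range(1, max_iter + 1):
        sweep(all_idx)
        polish_active_set()
        if np.max(np.abs(lam)) > 1e6:
            raise RuntimeError("no finite optimum: weights diverged (is a penalty zero?)")
        path.append(obj)
        if kkt_violation() <= tol:
            converged = True
            break

    q = np.exp(eta - logZ)
    entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())
    return MaxentModel(
        lambdas=lam,
        betas=betas,
        reg_multiplier=reg_multiplier,
        log_partition=logZ,
        entropy=entropy,
        n_presences=m,
        n_background=n,
        converged=converged,
        n_iter=it,
        objective_path=path,
        presence_mean=p_mean,
        background_expectation=q @ B,
        feature_kinds=kinds,
    )


# ---------------------------------------------------------------------------
# Prediction / projection
# ---------------------------------------------------------------------------

@dataclass
class SuitabilityMap:
    """Suitability raster on one epoch's grid.

    ``scale`` is "raw" (relative occurrence rate, sums to 1 over the
    training background), "cloglog" (bounded [0, 1]) or "truth" (a
    synthetic ground-truth map).
    """

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray
    scale: str
    epoch_label: str
    clamped: bool = False

    def valid_values(self) -> np.ndarray:
        v = self.values[self.mask]
        return v[np.isfinite(v)]


def predict(
    model: MaxentModel,
    expansion: FeatureExpansion,
    stack: BioclimStack,
    clamp: bool = True,
    extrapolate: bool = True,
    scale: str = "cloglog",
) -> SuitabilityMap:
    """Project the fitted model onto a climate stack.

    With ``clamp`` the projection climate is truncated to the training
    range before feature expansion; with ``extrapolate`` disabled, cells
    outside the training range become nodata instead.
    """
    if scale not in ("raw", "cloglog"):
        raise ValueError("scale must be 'raw' or 'cloglog'")
    rows, cols = stack.valid_cells()
    values = stack.cell_values(rows, cols)
    keep = np.ones(len(values), dtype=bool)
    if not extrapolate:
        keep = expansion.in_training_range(values)
    F = expansion.expand(values[keep], clamp=clamp)
    eta = F @ model.lambdas
    raw = np.exp(eta - model.log_partition)
    out_vals = raw if scale == "raw" else 1.0 - np.exp(-np.exp(model.entropy) * raw)
    grid = np.full(stack.mask.shape, np.nan)
    grid[rows[keep], cols[keep]] = out_vals
    mask = np.zeros_like(stack.mask)
    mask[rows[keep], cols[keep]] = True
    return SuitabilityMap(stack.geometry, grid, mask, scale, stack.epoch_label, clamped=clamp)


# ---------------------------------------------------------------------------
# Serialization (plain-text lambdas file + JSON metadata)
# ---------------------------------------------------------------------------

def save_model(model: MaxentModel, expansion: FeatureExpansion, path: str | Path) -> None:
    """Write a lambdas-style text file with a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# kind\tvars\tknot\tfeat_min\tfeat_max\tlambda\tbeta\n")
        for f, fmin, fmax, lam, beta in zip(
            expansion.features, expansion.feat_min, expansion.feat_max, model.lambdas, model.betas
        ):
            knot = "" if f.knot is None else f"{f.knot:.17g}"
            fh.write(
                f"{f.kind}\t{','.join(map(str, f.vars))}\t{knot}\t{fmin:.17g}\t{fmax:.17g}\t{lam:.17g}\t{beta:.17g}\n"
            )
    meta = {
        "var_min": expansion.var_min.tolist(),
        "var_max": expansion.var_max.tolist(),
        "log_partition": model.log_partition,
        "entropy": model.entropy,
        "reg_multiplier": model.reg_multiplier,
        "n_presences": model.n_presences,
        "n_background": model.n_background,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> tuple[MaxentModel, FeatureExpansion]:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    features, fmin, fmax, lams, betas = [], [], [], [], []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        kind, vars_s, knot_s, a, b, lam, beta = line.split("\t")
        features.append(
            FeatureDef(kind, tuple(int(v) for v in vars_s.split(",")), float(knot_s) if knot_s else None)
        )
        fmin.append(float(a))
        fmax.append(float(b))
        lams.append(float(lam))
        betas.append(float(beta))
    expansion = FeatureExpansion(
        np.array(meta["var_min"]), np.array(meta["var_max"]), features, np.array(fmin), np.array(fmax)
    )
    model = MaxentModel(
        lambdas=np.array(lams),
        betas=np.array(betas),
        reg_multiplier=meta["reg_multiplier"],
        log_partition=meta["log_partition"],
        entropy=meta["entropy"],
        n_presences=meta["n_presences"],
        n_background=meta["n_background"],
        converged=meta["converged"],
        n_iter=meta["n_iter"],
        feature_kinds=[f.kind for f in features],
    )
    return model, expansion
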