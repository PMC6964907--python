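"""Config-driven orchestration of the per-species workflow.

One species runs as: locality filters -> presence cells -> background
sample -> feature expansion -> maxent fit (per season) -> projection onto
each epoch's climate -> training-presence threshold -> binary range ->
distance to the focal site -> residency status per epoch, plus Levins
breadth per (season, epoch).  Batches continue past per-species failures,
recording error rows, and every output carries the config hash for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, maxent, range_mapping, status as status_mod, synthetic
from .breadth import NicheBreadthRecord, breadth_correlation, levins_breadth
from .data_io import BREEDING, SEASONS, WINTER, BioclimStack, OccurrenceSet
from .range_mapping import SeasonEpochPrediction, ThresholdRule
from .status import ResidencyStatus, classify_status

PRESENT = "present"


@dataclass(frozen=True)
class RunConfig:
    """All knobs of the per-species workflow, with checklist-study defaults.

    Defaults: presence distance D = 100 km, localities west of -104 deg
    only, optional >20 km thinning, up to 1500 records per season, study
    area = convex hull + 150 km buffer (or the full layer extent),
    10th-percentile training-presence threshold on cloglog output,
    regularization multiplier 1, up to 1000 optimizer iterations (5000 for
    the stricter no-clamping sensitivity variant).
    """

    site: tuple[float, float] = (-118.356, 34.063)  # La Brea vicinity
    D: float = 100.0
    lon_cutoff: float | None = -104.0
    thinning: bool = False
    thin_min_km: float = 20.0
    subsample_max: int = 1500
    background_mode: str = "mcp"  # or "full_extent"
    buffer_km: float = 150.0
    n_bg: int = 10_000
    reg_multiplier: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-5
    clamp: bool = True
    extrapolate: bool = True
    feature_classes: tuple[str, ...] | str = "auto"
    n_hinge_knots: int = 50
    threshold: ThresholdRule = field(default_factory=ThresholdRule)
    scale: str = "cloglog"
    seed: int = 0

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["threshold"] = dataclasses.asdict(self.threshold)
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class SpeciesResult:
    """Everything the pipeline computed for one species."""

    species_id: str
    predictions: dict[tuple[str, str], SeasonEpochPrediction]
    statuses: dict[str, ResidencyStatus]
    breadths: list[NicheBreadthRecord]
    filter_report: dict
    config_hash: str
    models: dict = field(default_factory=dict)  # season -> (MaxentModel, FeatureExpansion)

    def distance(self, season: str, epoch_label: str) -> float:
        return self.predictions[(season, epoch_label)].distance_km


def _prepare_occurrences(occ: OccurrenceSet, config: RunConfig, seed: int) -> tuple[OccurrenceSet, dict]:
    report = {"n_input": len(occ)}
    if config.lon_cutoff is not None:
        occ = data_io.filter_west_of(occ, config.lon_cutoff)
        report["n_after_lon_cutoff"] = len(occ)
    if config.thinning:
        occ = data_io.thin_occurrences(occ, config.thin_min_km, seed)
        report["n_after_thinning"] = len(occ)
    occ = data_io.subsample(occ, config.subsample_max, seed)
    report["n_after_subsample"] = len(occ)
    if len(occ) == 0:
        raise data_io.EmptyInputError(f"no records left after filtering for {occ.species_id}")
    return occ, report


def run_species(
    config: RunConfig,
    occurrences: dict[str, OccurrenceSet],
    stacks: dict[str, BioclimStack],
) -> SpeciesResult:
    """Run the full workflow for one species.

    ``occurrences`` maps season -> records; ``stacks`` maps epoch label ->
    climate stack and must contain the training epoch "present"; any other
    labels (e.g. "LGM-CCSM", "LGM-MIROC") are projection targets.
    """
    if PRESENT not in stacks:
        raise ValueError('stacks must include the training epoch "present"')
    species_id = next(iter(occurrences.values())).species_id
    rng = np.random.default_rng(config.seed)
    predictions: dict[tuple[str, str], SeasonEpochPrediction] = {}
    breadths: list[NicheBreadthRecord] = []
    models: dict = {}
    filter_report: dict = {}
    present_stack = stacks[PRESENT]
    for season in SEASONS:
        if season not in occurrences:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        occ, report = _prepare_occurrences(occurrences[season], config, sub_seed)
        rows, cols, pres_values, cell_report = maxent.extract_presence_cells(occ, present_stack)
        report.update(cell_report)
        filter_report[season] = report
        if config.background_mode == "full_extent":
            bg = maxent.full_extent_background(present_stack, config.n_bg, sub_seed)
        else:
            bg = maxent.build_background(occ, present_stack, config.buffer_km, config.n_bg, sub_seed)
        classes = (
            maxent.auto_feature_classes(len(rows))
            if config.feature_classes == "auto"
            else tuple(config.feature_classes)
        )
        expansion = maxent.FeatureExpansion.fit(bg.values, classes, config.n_hinge_knots)
        model = maxent.fit_maxent(
            expansion.expand(pres_values, clamp=True),
            expansion.expand(bg.values),
            reg_multiplier=config.reg_multiplier,
            max_iter=config.max_iter,
            tol=config.tol,
            feature_kinds=expansion.kinds,
        )
        train_map = maxent.predict(
            model, expansion, present_stack, clamp=config.clamp,
            extrapolate=config.extrapolate, scale=config.scale,
        )
        training_suits = train_map.values[rows, cols]
        training_suits = training_suits[np.isfinite(training_suits)]
        threshold = range_mapping.resolve_threshold(training_suits, config.threshold)
        for label, stack in stacks.items():
            suit = (
                train_map
                if label == PRESENT
                else maxent.predict(
                    model, expansion, stack, clamp=config.clamp,
                    extrapolate=config.extrapolate, scale=config.scale,
                )
            )
            rmap = range_mapping.binarize(suit, threshold)
            rmap.species_id, rmap.season = species_id, season
            dist = range_mapping.distance_to_site(rmap, config.site)
            predictions[(season, label)] = SeasonEpochPrediction(
                species_id, season, label, dist, threshold, rmap.n_present
            )
            breadths.append(levins_breadth(suit, species_id, season))
        models[season] = (model, expansion)
    statuses = {}
    for label in stacks:
        b = predictions.get((BREEDING, label))
        w = predictions.get((WINTER, label))
        statuses[label] = classify_status(
            b.distance_km if b else None, w.distance_km if w else None, config.D
        )
    return SpeciesResult(
        species_id, predictions, statuses, breadths, filter_report, config.hash(), models
    )


def run_batch(
    config: RunConfig,
    species_inputs: dict[str, dict[str, OccurrenceSet]],
    stacks: dict[str, BioclimStack],
) -> tuple[list[SpeciesResult], pd.DataFrame]:
    """Run many species; per-species failures become error rows, not aborts."""
    results, errors = [], []
    for species_id, occs in species_inputs.items():
        try:
            results.append(run_species(config, occs, stacks))
        except Exception as exc:  # noqa: BLE001 - batch robustness is the contract
            errors.append({"species_id": species_id, "error": f"{type(exc).__name__}: {exc}"})
    return results, pd.DataFrame(errors, columns=["species_id", "error"])


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _fmt_distance(d: float) -> str:
    return "NC" if not np.isfinite(d) else f"{d:.1f}"


def make_reports(
    results: list[SpeciesResult],
    outdir: str | Path,
    config: RunConfig,
    lgm_label: str | None = None,
    groups: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write the checklist-style report files and return their paths.

    Produces a per-species distance/status table, a shift cross-tabulation
    between the LGM and present epochs, a turnover JSON, breadth and
    breadth-correlation tables, and — when two LGM scenarios were run — a
    scenario-agreement table.  All counts are recomputed from the
    per-species rows.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    epoch_labels = sorted({label for r in results for (_, label) in r.predictions})
    lgm_labels = [e for e in epoch_labels if e != PRESENT]
    if lgm_label is None and lgm_labels:
        lgm_label = lgm_labels[0]

    # per-species table (distance/status checklist layout)
    rows = []
    for r in results:
        row: dict = {"species_id": r.species_id, "config_hash": r.config_hash}
        for label in epoch_labels:
            for season in SEASONS:
                pred = r.predictions.get((season, label))
                row[f"{label}_{season}_km"] = _fmt_distance(pred.distance_km) if pred else ""
            row[f"{label}_status"] = str(r.statuses.get(label, ""))
        rows.append(row)
    species_df = pd.DataFrame(rows, columns=["species_id", "config_hash"] if not rows else None)
    paths["species_table"] = outdir / "species_table.csv"
    species_df.to_csv(paths["species_table"], index=False)

    # shift table + turnover + summary between LGM and present
    if lgm_label is not None and results:
        tab_rows = [
            (
                r.species_id,
                (groups or {}).get(r.species_id, "inferred"),
                r.statuses[lgm_label],
                r.statuses[PRESENT],
            )
            for r in results
            if lgm_label in r.statuses and PRESENT in r.statuses
        ]
        shift = status_mod.cross_tabulate(tab_rows)
        paths["shift_table"] = outdir / "shift_table.csv"
        shift.to_frame().to_csv(paths["shift_table"])
        lgm_present = {r.species_id for r in results if r.statuses[lgm_label] in status_mod.PRESENCE_STATUSES}
        now_present = {r.species_id for r in results if r.statuses[PRESENT] in status_mod.PRESENCE_STATUSES}
        b = len(lgm_present - now_present)
        c = len(now_present - lgm_present)
        a = len(results) - b - c
        turnover: dict = {"a": a, "b": b, "c": c, "config_hash": config.hash()}
        try:
            turnover["simpson_turnover"] = status_mod.simpson_turnover(
                status_mod.TurnoverInput(a, b, c)
            )
        except ValueError:
            turnover["simpson_turnover"] = None
        paths["turnover"] = outdir / "turnover.json"
        paths["turnover"].write_text(json.dumps(turnover, indent=2))

    # breadth table and correlation matrix
    breadth_rows = [
        {
            "species_id": b.species_id,
            "season": b.season,
            "epoch": b.epoch_label,
            "B_raw": b.b_raw,
            "B_std": b.b_std,
            "n_cells": b.n_cells,
        }
        for r in results
        for b in r.breadths
    ]
    breadth_df = pd.DataFrame(
        breadth_rows, columns=["species_id", "season", "epoch", "B_raw", "B_std", "n_cells"]
    )
    paths["breadth"] = outdir / "breadth.csv"
    breadth_df.to_csv(paths["breadth"], index=False)
    if len(breadth_df) > 0:
        wide = breadth_df.pivot_table(index="species_id", columns=["epoch", "season"], values="B_std")
        wide.columns = [f"{e}_{s}" for e, s in wide.columns]
        corr_rows = []
        cols = list(wide.columns)
        for i, ci in enumerate(cols):
            for cj in cols[i + 1:]:
                pair = wide[[ci, cj]].dropna()
                if len(pair) >= 3 and pair[ci].std() > 0 and pair[cj].std() > 0:
                    r_val, p_val = breadth_correlation(pair[ci], pair[cj])
                    corr_rows.append({"x": ci, "y": cj, "pearson_r": r_val, "p_value": p_val, "n": len(pair)})
        paths["breadth_correlation"] = outdir / "breadth_correlation.csv"
        pd.DataFrame(corr_rows, columns=["x", "y", "pearson_r", "p_value", "n"]).to_csv(
            paths["breadth_correlation"], index=False
        )

    # scenario agreement between two LGM reconstructions
    if len(lgm_labels) >= 2:
        def run_frame(label):
            return pd.DataFrame(
                [
                    {"species_id": r.species_id, "season": season, "distance_km": r.distance(season, label)}
                    for r in results
                    for season in SEASONS
                    if (season, label) in r.predictions
                ]
            )

        cmp = status_mod.compare_scenarios(run_frame(lgm_labels[0]), run_frame(lgm_labels[1]), config.D)
        paths["scenario_agreement"] = outdir / "scenario_agreement.csv"
        cmp["table"].to_csv(paths["scenario_agreement"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Synthetic recovery battery
# ---------------------------------------------------------------------------

def battery_config(seed: int = 0) -> RunConfig:
    """Desk-scale configuration for the synthetic recovery battery.

    Linear + quadratic features (the ground-truth log-suitability is
    quadratic in climate), full-extent background (at this grid size every
    valid cell is used, so the background is exhaustive rather than
    sampled), no longitude cutoff (the synthetic grid is already regional).
    """
    return RunConfig(
        site=(-112.7, 38.1),
        lon_cutoff=None,
        background_mode="full_extent",
        max_iter=500,
        feature_classes=("linear", "quadratic"),
        seed=seed,
    )


def run_recovery_battery(
    n_species: int = 30,
    n_presence: int = 300,
    seed: int = 0,
    config: RunConfig | None = None,
) -> dict:
    """End-to-end parameter recovery on synthetic species.

    Generates a two-epoch synthetic climate, species with known niches and
    known true residency statuses at both epochs, samples presences,
    runs the full pipeline, and scores inferred against true statuses over
    all (species, epoch) pairs.
    """
    if config is None:
        config = battery_config(seed)
    grid = synthetic.default_battery_grid()
    present = synthetic.make_climate(grid, seed=seed, epoch_label=PRESENT)
    lgm = synthetic.apply_epoch_shift(present, synthetic.lgm_default_shift(), epoch_label="LGM")
    battery = synthetic.make_battery(
        n_species, present, lgm, config.site, config.threshold, config.D,
        seed=seed + 1, n_draws=n_presence,
    )
    stacks = {PRESENT: present, "LGM": lgm}
    rng = np.random.default_rng(seed + 2)
    records = []
    for spec, true_lgm, true_present in battery:
        occs = {
            season: synthetic.sample_presences(
                spec, present, season, n_presence, int(rng.integers(0, 2**31 - 1))
            )
            for season in SEASONS
        }
        result = run_species(config, occs, stacks)
        records.append(
            {
                "species_id": spec.species_id,
                "true_lgm": str(true_lgm),
                "true_present": str(true_present),
                "inferred_lgm": str(result.statuses["LGM"]),
                "inferred_present": str(result.statuses[PRESENT]),
            }
        )
    df = pd.DataFrame(records)
    correct = int((df.true_lgm == df.inferred_lgm).sum() + (df.true_present == df.inferred_present).sum())
    total = 2 * len(df)
    return {"table": df, "n_pairs": total, "n_correct": correct, "accuracy": correct / total}
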