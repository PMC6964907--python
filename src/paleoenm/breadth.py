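"""Levins niche breadth on suitability maps and cross-epoch comparisons.

Breadth is the inverse concentration of the normalized suitability
distribution: with p_i the suitability of cell i rescaled to sum to 1 over
the valid cells, B = 1 / sum(p_i^2).  B ranges from 1 (all suitability in
one cell) to n (uniform over n cells) and is standardized to [0, 1] as
(B - 1) / (n - 1).  Computed on the continuous map, not the thresholded
range, following the usual inverse-concentration implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .maxent import SuitabilityMap


@dataclass(frozen=True)
class NicheBreadthRecord:
    species_id: str | None
    season: str | None
    epoch_label: str | None
    b_raw: float
    b_std: float
    n_cells: int


def levins_breadth(
    suit: SuitabilityMap,
    species_id: str | None = None,
    season: str | None = None,
) -> NicheBreadthRecord:
    """Levins inverse-concentration breadth of a suitability map.

    Requires at least two valid cells and a non-zero map; invariant to
    positive rescaling of the suitabilities.
    """
    vals = suit.valid_values()
    n = vals.size
    if n < 2:
        raise ValueError("breadth needs at least 2 valid cells")
    if np.any(vals < 0):
        raise ValueError("suitabilities must be nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("breadth undefined for an all-zero suitability map")
    p = vals / total
    b_raw = 1.0 / float((p**2).sum())
    b_std = (b_raw - 1.0) / (n - 1.0)
    return NicheBreadthRecord(species_id, season, suit.epoch_label, b_raw, b_std, n)


def breadth_correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation between matched breadth scores.

    Pearson product-moment by default (two-sided p from the t distribution
    with n - 2 df); Spearman rank correlation with ``method="spearman"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired scores")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
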