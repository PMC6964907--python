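# Methods

`paleoenm` infers where bird species could live at the Last Glacial
Maximum (LGM, ~21 ka) from where they live now, and classifies their
seasonal residency at a focal fossil site at both epochs.  This note
documents the models, the numerical choices, and what the synthetic tests
do and do not establish.

## The niche model

The core is a presence-background maximum-entropy model (Maxent).  Given
presence records for one species and one season, and a background sample
of cells representing the available environment, the model is the Gibbs
distribution over background cells

    q(x) ∝ exp( Σ_j λ_j f_j(x) )

whose feature expectations match the presence means as closely as an L1
penalty allows.  Features f_j are derived from the 19 bioclimatic
variables (BIO1–BIO19) in the standard classes — linear, quadratic,
product, forward hinge, threshold — each rescaled to [0, 1] over the
background.  Feature classes default to the familiar sample-size ladder
(<10 presences: linear; 10–14: +quadratic; 15–79: +hinge; ≥80: +product)
and can be fixed explicitly.  Hinge knots are evenly spaced over each
variable's background range (50 per variable by default).

Fitting maximizes the penalized log-likelihood

    J(λ) = mean_presence[λ·f] − log Z(λ) − Σ_j β_j |λ_j|

by cyclic coordinate descent with soft-thresholding.  Each coordinate
takes a proximal Newton step followed by a backtracking line search, so J
is non-decreasing at every accepted step.  Coordinate descent identifies
the sparsity pattern quickly but tail-converges slowly on correlated
features, so after each full cycle the nonzero coordinates are polished
with a sign-fixed bounded quasi-Newton solve (the restricted problem is
smooth once the signs are fixed); polish steps are accepted only when
they do not decrease J.  Convergence is declared when the KKT violation
of the L1 optimum falls to
`tol` (default 1e−5); at that point the soft feature-matching bound
|E_presence f_j − E_q f_j| ≤ β_j holds to within `tol` for every feature.
Default penalties follow the published per-class tables, interpolated on
the presence count m and scaled by s_j/√m with s_j the presence standard
deviation of the feature (floored at 0.01 so presence-constant features
are not unpenalized); a global regularization multiplier (default 1)
scales all β_j.  Weights diverging past 1e6 raise an error (this can only
happen when a penalty is zero and the features separate presences from
background).

Duplicate presence records in one grid cell collapse to a single training
cell, and presences on nodata cells are dropped with a count — the usual
Maxent conventions.

**Output scales.**  Raw output is q normalized over the training
background; it sums to 1 there (checked to 1e−9) and transfers to other
epochs as exp(λ·f(x))/Z.  The bounded "suitability" used for thresholding
is the cloglog transform 1 − exp(−e^H q(x)), with H the entropy of the
fitted background distribution.  Projection onto another epoch's stack
either clamps covariates to the training range (default, mirroring common
practice) or, with extrapolation disabled, masks out-of-range cells as
nodata.

## Study area and background

The background is sampled uniformly without replacement from the valid
cells inside the study area: either the minimum convex polygon of the
occurrence records buffered by 150 km, or the full rectangular layer
extent (both modes are supported because published workflows use both).
The MCP and its buffer are constructed in a local spherical
azimuthal-equidistant projection (km units) about the record centroid —
a km buffer is ill-defined in degrees — and cell centers within 1 mm of
the boundary count as inside.  Fewer than three non-collinear records
fall back to a buffered bounding box, flagged on the result.

## Locality preparation

Occurrence tables are CSV with configurable longitude/latitude columns;
rows with unparsable or out-of-range coordinates are dropped and counted,
and exact duplicate coordinates collapse.  Three filters mirror common
practice for this kind of study: a strict longitude cutoff (default west
of −104°) restricting records to the region relevant to the site; spatial
thinning enforcing pairwise great-circle distances > 20 km (iterative
removal of the record with the most neighbors within the radius, ties
broken by a seed-fixed shuffle — deterministic per seed and equivalent in
spirit to the standard thinning packages); and uniform subsampling to at
most 1500 records.  Thinning is off by default and exposed as an optional
stage, since it is typically applied only in sensitivity analyses.  All
distances use the haversine formula on the WGS84 mean radius 6371.0088 km.

## Thresholding and residency classification

Suitability becomes presence/absence through the 10th-percentile
training-presence threshold: the k-th smallest training-presence
suitability with k = ceil(0.10 n) (nearest rank, no interpolation), the
largest cutoff at which at least 90% of training presences remain
predicted present.  The binarization rule is ≥ at the boundary, which
guarantees that retention property; a fixed-value threshold is available
for sensitivity work.  The threshold is resolved once per (species,
season) on the training epoch and applied unchanged to the projections.

The distance from the focal site to the predicted range is 0 if the
site's cell is predicted present, otherwise the minimum haversine
distance to any present cell center; an empty predicted range yields an
"NC" (not computed) sentinel that compares beyond any threshold.
Residency at an epoch follows from the two seasonal distances with
presence defined as ≤ D (default 100 km): both seasons → resident, one →
breeding-only or winter-only, neither → not present.  Migrant and extinct
statuses are never derived from distances; they come only from species
metadata.  Because the published checklist treats a distance of exactly
100 km inconsistently, the consistency checker reports rows at exactly D
to a boundary-conflict report instead of silently reconciling them.

Derived summaries: the shift table cross-tabulates (LGM status, present
status) by evidence group (documented / inferred / congeneric) and
refuses duplicate species; shifters are off-diagonal pairs where both
statuses are presence states; Simpson turnover is min(b, c)/[a + min(b, c)];
scenario agreement between two climate reconstructions compares within-D
verdicts per (species, season), counting both-absent as agreement.

## Niche breadth

Levins' inverse concentration B = 1/Σp_i² on the suitability map
normalized to sum 1 over valid cells, standardized to
B_std = (B − 1)/(n − 1).  Breadth is computed on the continuous cloglog
map over the projection extent, not the binarized range (the inverse
concentration convention); a common extent across epochs keeps n
comparable.  Cross-epoch comparisons use the Pearson product-moment
correlation with the two-sided t-based p-value; Spearman is available by
flag (the two conventions coexist in the literature this mirrors).

## The synthetic data and what passing tests show

The generator builds 19 smooth climate surfaces on a half-degree grid
(40×50 cells spanning roughly a western-North-America extent): 11
temperature-like layers (°C, cooling northward at 0.55–1.05 °C/degree)
and 8 precipitation-like layers (mm, wetting northward at 18–32
mm/degree), each with its own east-west slope and Gaussian-filtered
spatial noise (σ = 3 cells; amplitudes 0.4 °C and 15 mm).  The gradients
deliberately differ across layers so they span a two-dimensional signal
subspace: if every layer carried one shared trend, a fitted model could
express a niche through static between-layer noise contrasts that do not
move under an epoch displacement, and projection would be unidentified.
The default glacial contrast displaces every layer by the equivalent of
5° latitude southward (each layer's offset is its own north-south slope
times 5°, roughly −3 to −5 °C and +90 to +160 mm): cells take on the
climate currently found to their north, which keeps glacial climate
combinations inside the present-day climate space — the regime in which
presence-background models are transferable.  The affine per-layer shift
type also supports scalings and latitudinal gradients for non-analog
scenarios.

Species have Gaussian product-kernel niches: suitability
s(x) = prevalence · Π_j exp(−((e_j − μ_j)/σ_j)²/2), so log-suitability is
exactly quadratic in climate and a linear+quadratic maxent model can
represent the truth.  Battery species are limited by 4 randomly chosen
variables (width 0.75× that layer's spatial SD) and broadly tolerant of
the rest (10× SD), mirroring how real species respond sharply to a few
limiting factors.  Presences are multinomial draws proportional to
suitability, placed at cell centers with no within-cell jitter so
sampling and extraction coincide.

Ground-truth residency uses the same rules as the pipeline: per season a
threshold resolved on the present epoch and carried to the LGM map.  The
expectation-level analogue of the training-presence threshold weights
each cell by the probability it receives at least one of the n draws,
w_i = 1 − (1 − p_i)^n, matching the pipeline's collapse of duplicate
draws to distinct cells.

The recovery battery (30 species, 300 presences per season, exhaustive
full-extent background, linear+quadratic features, 500 optimizer cycles)
keeps only candidates with decisive ground truth: no true
season-epoch distance inside the band [0.5D, 2D], and true statuses
unchanged when the threshold is halved or doubled.  Species failing
either test sit on the classification boundary and carry no decisive
truth to recover.  Under these conditions the pipeline is required to
recover ≥95% of the 60 (species, epoch) statuses.

What this does **not** show about real data: the synthetic climates have
no orography, no coastlines or nodata structure, no sampling bias, and a
glacial contrast chosen to remain within the realized climate space.
Real LGM projections involve non-analog climates where any
presence-background model is partly unidentified — precisely why the
study design this package mirrors compares two independent glacial
reconstructions and asks only whether conclusions at the 100 km scale
agree.

## Problem sizes and determinism

Desk-scale defaults were chosen so the whole suite and the acceptance
script each run in minutes on one CPU: 40×50 climate grids, ≤2000
background cells, 300 presence draws per season, 30-species batteries.
All stochastic steps flow from a single integer seed through independent
spawned generators; a rerun with the same seed and config is
bit-identical, and every report row carries a hash of the full
configuration.

## Known limitations

- Only ESRI ASCII grids are read and written; there is no GeoTIFF I/O.
- Forward hinge features only (no reverse hinges); threshold features are
  off by default.
- No AUC/omission evaluation suite; model quality is assessed against
  synthetic ground truth instead.
- The Table-style checklist fixture hard-codes the published per-species
  rows, including two rows whose printed status contradicts the printed
  distances under the ≤100 km rule (see the classifier-consistency
  report); they are reported, not repaired.
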