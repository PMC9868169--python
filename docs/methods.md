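# Methods

## Grid model and conventions

All layers live on a shared `GridSpec`: a regular raster in one projected
CRS with square cells in meters. Cell `(i, j)` (0-based, rows increasing
southward) has center `x = origin_x + (j + 0.5)·cell`,
`y = origin_y − (i + 0.5)·cell`, where the origin is the outer north-west
corner of cell `(0, 0)`. Two grids are aligned iff all five spec fields are
equal; alignment resamples by index arithmetic at destination cell centers
(categorical layers always nearest-neighbor), and there is deliberately no
reprojection — centroid distances and Gi* distance bands are only
meaningful in projected meters, so CRS handling is the user's
responsibility and the CRS is an opaque label. Continuous grids use NaN as
the nodata sentinel so nodata propagates through arithmetic; categorical
grids reserve a legend code for nodata.

## Naturalness (LNI)

The per-class scores (arable 2, forest 0.67, grassland 1.33, artificial
water 6, natural water 0, urban/rural/industrial 10, unused 0) are the
operative LNI values on the 0–10 scale consistent with HDI's 0–60 range.
The coarser two-tier HAILS category table (CS1–CS3, FCS1–FCS5 on a 0–2
scale) is shipped as documentation metadata for the classification signs;
the mapping between the two scales is not reconciled — the per-class table
is authoritative and user-overridable via CSV for transfer to other
regions.

## Resource consumption (RCI)

Sectoral totals are spread as per-km² densities over their target classes
(default map: agriculture→arable, industry→industrial, urban public→urban,
forestry/husbandry→forest+grassland with proportional-area split,
transport→urban+rural+industrial since transport energy is not confined to
roads). Residential consumption is population density × per-capita rate on
urban and rural cells. Energy carriers are converted to standard coal
equivalent through a configurable factor table — factors are inputs of the
method, not constants. Allocation is strictly conservative (surface
integral equals input total to 1e-9 relative), uniform-density within each
class; zone-wise totals can be allocated zone-by-zone and mosaicked when
regional statistics are available. Temporal averaging windows are explicit
year sets (5-year blocks plus a closing 3-year block), validated for full
coverage. Sectors present in the statistics must be mapped or explicitly
ignored; silent dropping is an error. Resident-sector totals, when present,
are treated as bookkeeping (the per-capita route is authoritative) and
logged.

## Pollutant emissions (PEI)

Coarse CO₂/N₂O inventory fields are downscaled by ordinary kriging with a
zero-nugget exponential variogram fitted to the empirical semivariogram by
weighted least squares (weights ∝ pair counts per lag bin, 12 bins to half
the maximum pair distance). Zero nugget makes kriging an exact interpolator
at sample locations; a singular system falls back to IDW (power 2, 12
nearest neighbors) with a warning, and negative estimates are clamped to 0
and logged. The non-point surface is per-capita NOx on rural cells plus
`application_rate × (1 − effective_use_rate)` on arable cells, exactly 0
elsewhere — a hard invariant property-tested on random landscapes. The
diffuse-pollution index is reduced to its land-cover indicator (min–max
rescale to [0, 1], rank-preserving, affine-invariant); the distance, runoff
and slope indicators of the full index require DEM/soil inputs and are out
of scope.

## Standardization and combination

Raw surfaces are classified by Fisher–Jenks natural breaks: an exact
dynamic program over sorted distinct values with multiplicity weights,
O(k·n²), verified against exhaustive partition enumeration for n ≤ 12,
k ≤ 4. Inputs with more than 2,048 distinct values are first reduced to
2,048 quantile bins (weighted representatives) to keep desk-scale runtime;
the exact path is available via `max_exact`. Class boundaries are placed
midway between adjacent distinct values of neighboring classes, which makes
them strictly increasing and sends boundary ties to the lower class
deterministically.

Breaks are computed once on nonzero values pooled across all periods of a
dataset, so scores are temporally comparable. Exact zeros map to score 0
(no activity — keeps natural-water/unused cells at zero contribution and
reconciles the 0–10 range with k = 10 classes); nonzero cells get integer
scores 1..10. A pooled distribution with fewer than k distinct nonzero
values falls back to equal-interval breaks with a warning.

HDI = LNI + RCI + PEI cellwise with component-range validation
(≤ 10/20/30). Levels use equal-interval bins of width 6, half-open on the
right with the first bin closed at 0 — `[0,6], (6,12], …, (54,60]` — which
reproduces the integer row labels 0–6, 7–12, …, 55–60 without gaps.
Level-share tables report percentages of valid cells per zone, summing to
100 exactly before optional 2-decimal rounding.

## Spatial statistics

*Weights.* Rook/queen contiguity or a distance band over cell centers;
binary, symmetric, no self-neighbors. The weights scheme behind the
published autocorrelation statistics is not fixed by the method, so the
defaults are: queen contiguity with binary (non-row-standardized) weights
for Moran's I — the double-sum formula taken literally — and a binary band
of twice the cell size, including the self term, for Gi* (the starred
statistic). Both are configurable.

*Moran's I.* S² is the population variance (divide by n), which yields the
exact −1 identity on a rook checkerboard and the standard normalization.
The Z test uses the normality-assumption variance with E[I] = −1/(n−1); a
seeded permutation null (default 999 shuffles) is provided for
verification. The optimized sparse evaluation is tested to 1e-12 against
the brute-force double sum.

*Gi\*.* Z scores use the randomization moments
`Z = (Σwx − x̄·Wᵢ) / (S·√[(n·S1ᵢ − Wᵢ²)/(n−1)])`; categories follow
±1.645/±1.960/±2.576. A constant field is reported as all
`not_significant` with Z = 0 by convention (logged). On fields with a
planted cluster of ≥ 3 background SDs, ≥ 90% of cluster cells are flagged
hot95 or stronger (seeded simulation test).

*Centroids.* Cell-center coordinates weighted by HDI; segments report
Euclidean displacement, compass bearing (clockwise from north, also binned
to 8 winds), and speed = displacement / actual interval years. Note: one
published trajectory reports a 3-year segment at a speed implying division
by 5 years; this toolkit always divides by the true interval length.

## Synthetic landscapes

The generator emulates the study's input stack at toy scale: default
100×100 cells of 1 km, seven periods labeled 1990–2018, arable-dominated
class proportions (50% arable, 18% settlement/industrial, 20%
forest/grass/water, 3% unused), urban density lognormal around
2,500 persons/km² vs 400 rural (basin-scale mean of order 600), sector
totals following per-sector multiplicative trends, and coarse emission
fields at 4× cell size with plantable clusters whose ground-truth masks
feed the hot-spot recovery tests. Land-use clustering comes from
thresholding Gaussian-smoothed seeded noise at class-proportion quantiles:
shares then match proportions almost exactly while spatial autocorrelation
rises with the smoothing sigma. One integer seed determines every output
bit-exactly.

What the generator does *not* emulate: real land-use change dynamics
(parcels persist across periods only trivially), demographic structure,
seasonal consumption cycles, or spatially correlated statistical reporting
errors. Passing tests therefore demonstrate the correctness and invariance
of the computational pipeline — conservation, determinism, analytic limits,
recovery of planted structure — not the empirical accuracy of any regional
disturbance assessment.

## Problem sizes and numerical choices

Tests run the pipeline end-to-end on 30–60 cell grids with 3 periods, and
the statistics on up to 50×50 fields with 10,000-shuffle permutation
checks; these sizes keep the whole suite to seconds while exercising every
code path at full fidelity. Tolerances: conservation 1e-9 relative, oracle
equivalence 1e-12 absolute (Moran) and 1e-9 (Jenks SSD), kriging exactness
1e-6 relative at samples. Degenerate inputs (zero variance, zero-sum
fields, < k distinct values, empty zones) raise typed errors rather than
returning silent defaults, except where a convention is documented
(constant-field Gi*, equal-interval fallback).
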