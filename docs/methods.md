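# Methods

This note documents the model implemented by `resilscape`, the choices made
where the method leaves room, and what the synthetic scenes do and do not
establish.

## Grid model and focal windows

All layers of one run live on a single grid: same shape, cell size
(nominally 90 m), origin and CRS tag.  Mismatches are hard errors — the
pipeline never resamples silently, because inputs are expected to be
co-registered upstream.

A focal window of radius *r* px contains every cell whose center-to-center
distance from the focal cell is ≤ *r* (integer-exact membership via
`dy² + dx² ≤ r²`), the center included.  Windows clip at raster edges (no
wrap-around).  Nodata handling is one-way: nodata neighbors are excluded
from every statistic, valid centers always get a value unless their whole
window is nodata, and nodata centers stay nodata.

Sum-based statistics (mean, weighted mean, the z-score's mean and
sum-of-squares) use direct correlation for small footprints and FFT
convolution once the footprint exceeds ~2000 cells; both paths are verified
against a brute-force per-cell loop to 1e-9.  Order statistics (range,
distinct counts) use exact max/min filters and per-code dilation, and match
the loop exactly.  The moving z-score centers the layer on its global mean
first — z-scores are shift-invariant, and this keeps the windowed variance
well conditioned (a flat layer yields exactly zero variance on either
path).

Windowed z-scores use the **population** standard deviation; at the window
sizes involved (hundreds to tens of thousands of cells) the sample/
population distinction is negligible, and one convention keeps runs
bit-reproducible.  Where the local sd is zero the z-score is defined as 0:
a locally flat layer contributes no heterogeneity signal, rather than
becoming nodata.

Default radii (90 m cells): 5 px (~450 m) for landform variety, elevation
range, TPI, local wetland density and soil richness; 13 px (~1170 m) for
the regional wetland window; 23 px (~2070 m) for connectedness; 200 px for
z-score standardization.  The 200 px window exists so that standardization
sees a mix of physical settings and transitions smoothly across region
boundaries instead of being re-standardized per zone.  A `strict_circular`
flag can swap the z-score's circular window for its bounding square; the
default stays circular.

## Terrain metrics and the landform taxonomy

Slope and aspect come from the Horn 3×3 plane fit (edge rows replicate;
nodata neighbors take the center value so valid centers survive).  Aspect
is the downslope azimuth, undefined (flagged) on flats.  TPI is elevation
minus the focal mean elevation (default radius 5 px — the same scale as the
variety window, chosen so the two terrain components describe the same
neighborhood).  The moisture accumulation index is
`ln((A + 1)/tan(max(slope, 0.57°)))` with *A* the D8 upslope cell count —
the standard topographic wetness form; the 0.57° floor (tan ≈ 0.01) keeps
it finite on flats.  D8 routing sends each cell's flow to its steepest
downslope neighbor, ties broken by a fixed scan order, flats and pits
unrouted; the whole chain is deterministic.

Landform classification is an ordered first-match rule cascade over
(slope, TPI, moisture, equator-facing), shipped as data so it can be
re-calibrated without code changes.  The default ten classes:

| code | class | rule (first match wins) |
|---|---|---|
| 6 | cliff | slope > 40° |
| 10 | summit | TPI > 5 m and slope ≤ 2° |
| 9 | ridge/hilltop | TPI > 5 m |
| 8 | moist valley | TPI < −5 m and moisture > 6 |
| 7 | valley/toeslope | TPI < −5 m |
| 4 | dry steep slope | slope > 15° and equator-facing |
| 5 | cool steep slope | slope > 15° |
| 3 | gentle slope | slope > 2° |
| 2 | wet flat | moisture > 6 |
| 1 | flat plain | always |

Aspect enters only through the equator-facing/pole-facing split of steep
slopes (hemisphere from the sign of the grid origin's y coordinate) — the
minimal use that captures the solar-radiation contrast.  The last rule must
be unconditional; a non-exhaustive cascade is rejected at load time.
Thresholds are in the metric's natural units (degrees, meters, index
units) and were fixed once from their physical meaning: ±5 m TPI is about
one DEM vertical-error unit of relief at 90 m cells, moisture 6
corresponds to a few-hundred-cell upslope area on gentle ground.

## Heterogeneity components and combination

*Elevation range residuals.* The focal range correlates with landform
variety by construction, so the range is regressed on variety (OLS over
all valid cells) and the residual is kept.  Residuals sum to zero and are
uncorrelated with variety whenever the regression runs; if variety is
constant the slope is undefined and the residual falls back to
range − mean(range), flagged on the returned fit.

*Wetland score.* Base score = mean(local density, regional density).
Patchiness (global 8-connected patch labels, distinct labels counted per
regional window) is rescaled to [0, 1] by its extent-wide maximum — raw
patch counts are not commensurable with densities — and the double-
weighted average `(2·local + regional + patchiness)/4` applies wherever it
raises the score.  Because that average exceeds the base by exactly
`(patchiness − regional)/4`, this "apply where beneficial" form is
equivalent to branching on patchiness > regional density; it was chosen
over branching on patchiness > base score because the latter makes the
score discontinuously *drop* at the branch in some configurations,
violating the monotonicity a habitat-amount score should have (adding
wetland should never reduce it).  The score is bounded in [0, 1] and
nondecreasing in every input.

*Combination.* With all four components z-scored, the aggregate starts at
the landform-variety z-score and each candidate — elevation range, then
wetland score, then soil richness, a fixed order — fires only where it
exceeds the current aggregate: `h ← (2h + z)/3`.  Comparing against the
*running aggregate* (not against the landform z-score alone) makes each
update well defined and scale-free, and reusing the 2:1 form at every step
keeps landform variety's cumulative weight the largest.  The aggregate can
only move up, so combined heterogeneity ≥ the landform-variety z-score
everywhere; no separate flat-area branch is needed, because on flats the
terrain z-scores are low and the wetland/soil updates fire naturally.  The
combined layer is not re-standardized — quartiling is rank-based, so a
final standardization would not change the classification.

## Resistance and connectedness

The resistance table maps every land-cover code to a resistance ≥ 1; codes
without an entry are an error (no silent default).  The shipped default
spans the natural→urban gradient — natural forest/wetland/grassland 1,
secondary vegetation 5, pasture 20, annual cropland 40, mining/bare 70,
roads 80, urban 100 — with river classes by width (narrow 2, medium 30,
wide 90).  These are ordinal stand-ins preserving the natural < impacted <
urban ordering and are fully user-overridable.

The kernel weight at distance *d* is proportional to `1 − d/(r+1)`,
strictly positive at the rim (the decay reaches zero just *beyond* the
window); weights are renormalized over the valid in-bounds cells of each
window so edge cells remain true means rather than deflated sums.
Connectedness is the reciprocal of the weighted mean resistance, giving
(0, 1] with 1 = fully natural surroundings; a `complement` mode (linear
flip over the observed resistance span) is available for users who prefer
an additive scale.  Reciprocal is the default reading of "inverse".
Connectedness is antitone in every resistance entry and equals exactly
1/r on a uniform landscape.

## Classification and accounting

Quartile breaks are the empirical 25/50/75 percentiles (linear
interpolation; nearest-rank variants selectable) over all valid cells of
the extent.  Bins are upper-inclusive (value ≤ break → lower bin), fixed
for determinism; with continuous layers each marginal bin holds 25% ± 1
cell, while heavily tied integer layers can be unbalanced — an inherent
property of quartiling ties, not an implementation artifact.  The class
code is `10·bin(connectedness) + bin(heterogeneity)`; the quadrant
partition is exactly Q1{11,12,21,22}, Q2{13,14,23,24}, Q3{31,32,41,42},
Q4{33,34,43,44}.  Classification is invariant under any strictly
increasing transform of a layer (it only sees ranks).

Water cells are set to nodata after classification and appear in no
summary row.  Zonal summaries report counts and percentages per (zone,
class) and (zone, quadrant), within-zone and across-extent, rounded to one
decimal by largest remainder within each accounting group so printed
totals are exactly 100.0.  A zone with no classified cells is emitted with
zero counts and NaN within-zone percentages.

## Synthetic scenes

`make_scene` emulates the *structure* of the pipeline's real-world inputs,
not any region's statistics: fractal (spectral-synthesis, Hurst 0.8),
cone, ridge-valley or plane terrain; wetlands as smoothed-noise clusters
biased to low ground through a logistic of DEM rank (floodplain-style);
soils and land cover as nearest-seed Voronoi mosaics (seed counts
allocated to classes by largest remainder, so realized fractions track the
recipe within ~2 percentage points at 256×256); optional 1 px roads and a
meandering river of configured width; zones as vertical bands.  Everything
is deterministic under (config, seed).

`make_gradient_scene` is the study scene for end-to-end checks: shared
rough terrain, natural cover left, cropland/pasture/urban mosaic right, so
heterogeneity is similar across halves while connectedness differs
sharply.  The desk-scale default is 256×256 cells (a ~23 × 23 km scene at
90 m) — large enough for the 23 px connectedness window and the quartile
statistics to be meaningful, small enough that the full pipeline runs in
seconds.

What passing on these scenes shows: the machinery (windows, z-scores,
regression, kernel, quartiling, accounting) is correct, and the
classification separates a permeable from a converted landscape as the
method intends.  What it does not show: that the default taxonomy
thresholds or resistance values are calibrated for any real region —
those are declared stand-ins meant to be replaced by user configuration,
and real DEM noise, registration error and class imbalance are not
emulated.

## Known limitations

- D8 flow accumulation does not route through flats or pits; broad flat
  valleys under-accumulate relative to hydrologically conditioned DEMs.
- Patchiness rescaling by the extent-wide maximum ties the wetland score
  to the analysis extent; cropping the extent can change scores.
- Quartile breaks over the full extent mean class labels are relative to
  the scene analyzed, not absolute — by design, but it implies maps from
  different extents are not directly comparable.
- Connectedness is structural (species-agnostic); no dispersal kernels,
  least-cost paths or circuit theory.
- No reprojection, resampling, multi-band imagery or tiled out-of-core
  processing; inputs must arrive co-registered.
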