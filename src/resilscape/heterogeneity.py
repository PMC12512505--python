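"""Landscape heterogeneity: component layers and their combination.

Landscape heterogeneity proxies the variety of microclimates around a
cell.  It is built from four components:

a. landform variety (see :mod:`resilscape.landform`);
b. elevation range residuals -- the focal elevation range (max - min in a
   ~450 m window) with the part explained by landform variety removed by
   ordinary least squares, so the two components are uncorrelated;
c. wetland score -- local (~450 m) and regional (~1170 m) wetland density
   plus regional wetland patchiness, since wetlands stabilize
   microclimates in flat landscapes where terrain metrics carry no
   signal;
d. soil richness -- the count of distinct soil types in the ~450 m
   window.

Each component is standardized to a moving-window z-score (200 px radius
by default, giving a smooth transition between regions instead of
per-zone standardization), then combined hierarchically: the aggregate
starts at the landform-variety z-score, and each further component, in
the fixed order elevation range -> wetland score -> soil richness,
updates the aggregate only where it exceeds it, as
``h := (2*h + z)/3``.  The running aggregate carries double weight, so
landform variety retains the largest cumulative weight everywhere, while
in flat terrain (where the terrain z-scores are low) the wetland and
soil components take over naturally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from resilscape.raster_core import (
    Grid,
    NeighborhoodSpec,
    ensure_congruent,
    focal_apply,
    moving_zscore,
)

__all__ = [
    "RegressionFit",
    "HeterogeneityComponents",
    "elev_range_residuals",
    "wetland_components",
    "wetland_score",
    "soil_richness",
    "combine_heterogeneity",
    "heterogeneity_components",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of focal elevation range on landform variety.

    ``degenerate`` flags the constant-variety fallback, where the slope is
    undefined and residuals are taken about the mean range instead.
    """

    slope: float
    intercept: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class HeterogeneityComponents:
    """The four moving-window z-scored component layers."""

    z_landform_variety: Grid
    z_elev_range_resid: Grid
    z_wetland_score: Grid
    z_soil_richness: Grid

    def layers(self) -> tuple[Grid, Grid, Grid, Grid]:
        return (
            self.z_landform_variety,
            self.z_elev_range_resid,
            self.z_wetland_score,
            self.z_soil_richness,
        )


def elev_range_residuals(
    dem: Grid, variety: Grid, spec: NeighborhoodSpec | None = None
) -> tuple[Grid, RegressionFit]:
    """Focal elevation range, decorrelated from landform variety.

    The raw range (max - min elevation in the window) correlates with
    landform variety by construction; a simple linear regression of range
    on variety across all valid cells removes that shared part, and the
    residuals are the component of elevation range not explained by
    variety.  If variety is constant the slope is undefined and the
    residual falls back to range minus its mean (flagged on the fit).
    """
    if spec is None:
        spec = NeighborhoodSpec(radius_px=5)
    ensure_congruent(dem, variety)
    rng = focal_apply(dem, spec, "range")
    both = rng.valid & variety.valid
    x = variety.values[both].astype(float)
    y = rng.values[both].astype(float)
    n = int(both.sum())
    if n < 2 or np.ptp(x) == 0:
        mean_y = float(y.mean()) if n else 0.0
        resid = rng.masked(fill=np.nan) - mean_y
        fit = RegressionFit(slope=0.0, intercept=mean_y, n=n, degenerate=True)
    else:
        slope, intercept = np.polyfit(x, y, deg=1)
        resid = rng.masked(fill=np.nan) - (
            slope * variety.masked(fill=np.nan) + intercept
        )
        fit = RegressionFit(slope=float(slope), intercept=float(intercept), n=n)
    mask = rng.nodata_mask | variety.nodata_mask
    resid[mask] = np.nan
    return rng.with_values(resid, nodata_mask=mask), fit


def wetland_components(
    wetlands: Grid,
    local_spec: NeighborhoodSpec | None = None,
    regional_spec: NeighborhoodSpec | None = None,
) -> tuple[Grid, Grid, Grid]:
    """Local density, regional density, and regional patchiness of wetlands.

    Densities are focal means of the binary wetland layer (fractions in
    [0, 1]).  Patchiness is the number of wetlands in the regional window:
    wetland cells are labeled once globally into 8-connected patches and
    each window counts the distinct patches it intersects.
    """
    if local_spec is None:
        local_spec = NeighborhoodSpec(radius_px=5)
    if regional_spec is None:
        regional_spec = NeighborhoodSpec(radius_px=13)
    vals = wetlands.masked(fill=np.nan)
    bad = wetlands.valid & ~np.isin(np.nan_to_num(vals, nan=0.0), (0.0, 1.0))
    if bad.any():
        raise ValueError("wetland layer must be binary (0/1/nodata)")

    local_density = focal_apply(wetlands, local_spec, "mean")
    regional_density = focal_apply(wetlands, regional_spec, "mean")

    labels, n_patches = ndimage.label(
        (wetlands.values == 1) & wetlands.valid, structure=np.ones((3, 3), dtype=int)
    )
    fp = regional_spec.footprint()
    present = np.zeros(wetlands.shape, dtype=np.int64)
    for lab in range(1, n_patches + 1):
        hit = (labels == lab).astype(np.uint8)
        present += ndimage.maximum_filter(hit, footprint=fp, mode="constant", cval=0)
    patch = present.astype(float)
    patch[wetlands.nodata_mask] = np.nan
    patchiness = wetlands.with_values(patch, nodata_mask=wetlands.nodata_mask)
    return local_density, regional_density, patchiness


def wetland_score(
    local_density: Grid, regional_density: Grid, regional_patchiness: Grid
) -> Grid:
    """Combine wetland densities and patchiness into one score.

    The base score is the mean of local and regional density.  Where
    patchiness -- rescaled to [0, 1] by its extent-wide maximum, so a raw
    patch count becomes commensurable with densities -- dominates, the
    score upgrades to the weighted average
    ``(2*local + regional + patchiness)/4``, local density carrying twice
    the weight of the other two.  Since the upgraded average exceeds the
    base by exactly ``(patchiness - regional)/4``, the upgrade is applied
    wherever it raises the score (``score = max(base, upgraded)``), which
    keeps the score in [0, 1] and nondecreasing in every input.
    """
    ensure_congruent(local_density, regional_density, regional_patchiness)
    ld = local_density.masked(fill=np.nan)
    rd = regional_density.masked(fill=np.nan)
    pt = regional_patchiness.masked(fill=np.nan)
    pmax = np.nanmax(pt) if np.isfinite(pt).any() else 0.0
    pt_scaled = pt / pmax if pmax > 0 else np.zeros_like(pt)
    base = (ld + rd) / 2.0
    upgraded = (2.0 * ld + rd + pt_scaled) / 4.0
    score = np.maximum(base, upgraded)
    mask = (
        local_density.nodata_mask
        | regional_density.nodata_mask
        | regional_patchiness.nodata_mask
    )
    score[mask] = np.nan
    return local_density.with_values(score, nodata_mask=mask)


def soil_richness(soils: Grid, spec: NeighborhoodSpec | None = None) -> Grid:
    """Distinct soil types within the circular window of each cell."""
    if spec is None:
        spec = NeighborhoodSpec(radius_px=5)
    return focal_apply(soils, spec, "count_distinct")


def combine_heterogeneity(components: HeterogeneityComponents) -> Grid:
    """Hierarchical combination of the four z-scored components.

    Starting from the landform-variety z-score, each candidate component
    (elevation range, then wetland score, then soil richness -- the order
    is fixed) updates the aggregate only at cells where it exceeds it:
    ``h := (2*h + z)/3``.  The aggregate side carries double weight, so
    the first update reproduces the landform-double-weighted average and
    landform variety keeps the largest cumulative weight overall.  The
    result is never below the landform-variety z-score.
    """
    z_lv, z_er, z_ws, z_sr = components.layers()
    ensure_congruent(z_lv, z_er, z_ws, z_sr)
    h = z_lv.masked(fill=np.nan)
    mask = z_lv.nodata_mask.copy()
    for cand_grid in (z_er, z_ws, z_sr):
        z = cand_grid.masked(fill=np.nan)
        mask |= cand_grid.nodata_mask
        with np.errstate(invalid="ignore"):
            fire = z > h
        h = np.where(fire, (2.0 * h + z) / 3.0, h)
    h[mask] = np.nan
    return z_lv.with_values(h, nodata_mask=mask)


def heterogeneity_components(
    variety: Grid,
    elev_resid: Grid,
    wet_score: Grid,
    soil_rich: Grid,
    *,
    zscore_spec: NeighborhoodSpec | None = None,
    strict_circular: bool = True,
) -> HeterogeneityComponents:
    """Standardize the four raw component layers to moving-window z-scores."""
    if zscore_spec is None:
        zscore_spec = NeighborhoodSpec(radius_px=200)
    zs = [
        moving_zscore(g, zscore_spec, strict_circular=strict_circular)
        for g in (variety, elev_resid, wet_score, soil_rich)
    ]
    return HeterogeneityComponents(*zs)
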