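"""Grid data model and circular focal-window machinery.

Every layer in a pipeline run lives on one shared georeferenced grid
(nominally 90 m cells).  Focal statistics are computed over a circular
neighborhood -- all cells whose center-to-center distance is at most the
pixel radius, center included -- clipped at raster edges (no wrap-around).
Nodata cells never contribute to a statistic but do not poison valid
centers; a center whose whole neighborhood is nodata yields nodata.

Two implementations are provided for every statistic: a fast vectorized
path and a brute-force per-cell loop (`focal_apply_bruteforce`) kept as
the reference oracle.  The fast path must agree with the loop exactly for
discrete statistics (range, count_distinct) and to 1e-9 for means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "Grid",
    "Kernel",
    "NeighborhoodSpec",
    "GridAlignmentError",
    "ensure_congruent",
    "radius_to_pixels",
    "circular_footprint",
    "focal_apply",
    "focal_apply_bruteforce",
    "moving_zscore",
]

# Footprints above this many cells switch the sum-based statistics to FFT
# convolution; below it, direct correlation is used.
_FFT_FOOTPRINT_CUTOFF = 2000


class GridAlignmentError(ValueError):
    """Raised when layers of one pipeline run do not share a grid."""


class Kernel(str, Enum):
    UNIFORM = "uniform"
    LINEAR_DECAY = "linear_decay"


@dataclass(frozen=True)
class Grid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values
        2-D array; units depend on the layer (m for a DEM, dimensionless
        scores, integer class codes).
    cell_size
        Ground distance per cell edge, in meters; must be positive.
    origin
        (x, y) of the upper-left corner.  The sign of the y (latitude-like)
        coordinate decides the hemisphere for aspect-based rules.
    crs_tag
        Opaque coordinate-system identifier; compared verbatim.
    nodata_mask
        Boolean array, True where the cell is invalid.  Defaults to
        all-valid (plus wherever ``values`` is NaN).
    """

    values: np.ndarray
    cell_size: float = 90.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "local"
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got shape {vals.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        mask = self.nodata_mask
        if mask is None:
            mask = np.zeros(vals.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool).copy()
            if mask.shape != vals.shape:
                raise ValueError("nodata_mask shape does not match values")
        if np.issubdtype(vals.dtype, np.floating):
            mask |= np.isnan(vals)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "nodata_mask", mask)

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return ~self.nodata_mask

    def with_values(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "Grid":
        """New grid on the same georeference carrying different values."""
        if nodata_mask is None:
            nodata_mask = self.nodata_mask
        return replace(self, values=values, nodata_mask=nodata_mask)

    def masked(self, fill: float = np.nan) -> np.ndarray:
        """Float copy of the values with nodata replaced by ``fill``."""
        out = np.array(self.values, dtype=float)
        out[self.nodata_mask] = fill
        return out

    def congruent_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and self.crs_tag == other.crs_tag
        )


def ensure_congruent(*grids: Grid) -> None:
    """Fail fast if the layers do not share shape, cell size, origin and crs.

    Silent resampling hides bugs; any mismatch is a hard error.
    """
    if not grids:
        return
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            raise GridAlignmentError(
                f"layer {i} shape {g.shape} != layer 0 shape {ref.shape}"
            )
        if not np.isclose(g.cell_size, ref.cell_size):
            raise GridAlignmentError(
                f"layer {i} cell_size {g.cell_size} != layer 0 cell_size {ref.cell_size}"
            )
        if not np.allclose(g.origin, ref.origin):
            raise GridAlignmentError(
                f"layer {i} origin {g.origin} != layer 0 origin {ref.origin}"
            )
        if g.crs_tag != ref.crs_tag:
            raise GridAlignmentError(
                f"layer {i} crs_tag {g.crs_tag!r} != layer 0 crs_tag {ref.crs_tag!r}"
            )


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular focal window: radius in pixels plus a kernel shape.

    The cell set is every cell whose center-to-center distance from the
    focal cell is <= ``radius_px`` (the center itself included).  For the
    linear-decay kernel, weights fall linearly with distance, stay
    strictly positive at the rim, and are normalized to sum to 1 over the
    valid cells actually present in the window.
    """

    radius_px: int
    kernel: Kernel = Kernel.UNIFORM

    def __post_init__(self) -> None:
        if int(self.radius_px) < 1:
            raise ValueError(f"radius_px must be >= 1, got {self.radius_px}")
        object.__setattr__(self, "radius_px", int(self.radius_px))
        object.__setattr__(self, "kernel", Kernel(self.kernel))

    def footprint(self) -> np.ndarray:
        return circular_footprint(self.radius_px)

    def weights(self) -> np.ndarray:
        """Unnormalized weight stencil ((2r+1)², zero outside the circle)."""
        r = self.radius_px
        fp = circular_footprint(r)
        if self.kernel is Kernel.UNIFORM:
            return fp.astype(float)
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        dist = np.hypot(dy, dx)
        # Decay hits zero just beyond the rim (denominator r+1) so the
        # outermost ring keeps positive weight.
        w = (1.0 - dist / (r + 1.0)) * fp
        return w


def radius_to_pixels(radius_m: float, cell_size: float) -> int:
    """Convert a ground-distance window radius to whole pixels.

    A 450 m radius on a 90 m grid is 5 px; 1170 m is 13 px.  Rounds to the
    nearest pixel with a floor of 1.
    """
    if not radius_m > 0 or not cell_size > 0:
        raise ValueError(
            f"radius_m and cell_size must be > 0, got {radius_m}, {cell_size}"
        )
    return max(1, round(radius_m / cell_size))


def circular_footprint(radius_px: int) -> np.ndarray:
    """Boolean disk: True where dy² + dx² <= r² (integer-exact membership)."""
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dy * dy + dx * dx) <= r * r


# ---------------------------------------------------------------------------
# focal statistics -- fast paths
# ---------------------------------------------------------------------------

_VALID_STATS = ("mean", "range", "count_distinct", "weighted_mean")


def _focal_sum(arr: np.ndarray, stencil: np.ndarray) -> np.ndarray:
    """Sum of arr over the stencil at every cell, zero-padded at edges."""
    if int(np.count_nonzero(stencil)) > _FFT_FOOTPRINT_CUTOFF:
        out = signal.fftconvolve(arr, stencil[::-1, ::-1], mode="same")
        return out
    return ndimage.correlate(arr, stencil.astype(float), mode="constant", cval=0.0)


def focal_apply(grid: Grid, spec: NeighborhoodSpec, stat: str) -> Grid:
    """Per-cell statistic over the valid cells of the circular neighborhood.

    ``stat`` is one of mean, range, count_distinct, weighted_mean.
    weighted_mean uses the spec's kernel weights (equal weights if the
    kernel is uniform), renormalized over the valid cells present in each
    window.  Output is nodata where the center is nodata or the window
    holds no valid cell.
    """
    if stat not in _VALID_STATS:
        raise ValueError(f"unknown stat {stat!r}; expected one of {_VALID_STATS}")
    if not grid.valid.any():
        raise ValueError("grid has no valid cells")

    fp = spec.footprint()
    valid = grid.valid.astype(float)
    vals = grid.masked(fill=0.0)

    if stat in ("mean", "weighted_mean"):
        w = spec.weights() if stat == "weighted_mean" else fp.astype(float)
        wsum = _focal_sum(vals * valid, w)
        wnorm = _focal_sum(valid, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = wsum / wnorm
        empty = wnorm <= 1e-12
    elif stat == "range":
        hi = grid.masked(fill=-np.inf)
        lo = grid.masked(fill=np.inf)
        mx = ndimage.maximum_filter(hi, footprint=fp, mode="constant", cval=-np.inf)
        mn = ndimage.minimum_filter(lo, footprint=fp, mode="constant", cval=np.inf)
        out = mx - mn
        counts = ndimage.correlate(valid, fp.astype(float), mode="constant", cval=0.0)
        empty = np.rint(counts) < 1
    else:  # count_distinct
        codes = np.unique(grid.values[grid.valid])
        present = np.zeros(grid.shape, dtype=np.int64)
        for code in codes:
            hit = ((grid.values == code) & grid.valid)
            dil = ndimage.maximum_filter(
                hit.astype(np.uint8), footprint=fp, mode="constant", cval=0
            )
            present += dil
        out = present.astype(float)
        counts = ndimage.correlate(valid, fp.astype(float), mode="constant", cval=0.0)
        empty = np.rint(counts) < 1

    out = np.asarray(out, dtype=float)
    mask = grid.nodata_mask | empty
    out[mask] = np.nan
    return grid.with_values(out, nodata_mask=mask)


def focal_apply_bruteforce(grid: Grid, spec: NeighborhoodSpec, stat: str) -> Grid:
    """Reference per-cell loop for `focal_apply`; the oracle the fast path
    is tested against.  O(n·k) python loop -- small grids only."""
    if stat not in _VALID_STATS:
        raise ValueError(f"unknown stat {stat!r}; expected one of {_VALID_STATS}")
    r = spec.radius_px
    fp = spec.footprint()
    wts = spec.weights() if stat == "weighted_mean" else fp.astype(float)
    nrow, ncol = grid.shape
    out = np.full(grid.shape, np.nan)
    mask = np.ones(grid.shape, dtype=bool)
    vals = grid.values
    valid = grid.valid
    for i in range(nrow):
        for j in range(ncol):
            if not valid[i, j]:
                continue
            members: list[float] = []
            weights: list[float] = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not fp[di + r, dj + r]:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nrow and 0 <= jj < ncol and valid[ii, jj]:
                        members.append(float(vals[ii, jj]))
                        weights.append(float(wts[di + r, dj + r]))
            if not members:
                continue
            mask[i, j] = False
            if stat == "mean":
                out[i, j] = sum(members) / len(members)
            elif stat == "range":
                out[i, j] = max(members) - min(members)
            elif stat == "count_distinct":
                out[i, j] = len(set(members))
            else:
                wsum = sum(weights)
                out[i, j] = sum(m * w for m, w in zip(members, weights)) / wsum
    return grid.with_values(out, nodata_mask=mask)


def moving_zscore(
    grid: Grid,
    spec: NeighborhoodSpec | None = None,
    *,
    strict_circular: bool = True,
) -> Grid:
    """Per-cell (value - local mean) / local sd over a moving window.

    The default window radius is 200 px, large enough to span distinct
    physical settings while giving a smooth transition between regions.
    The sd is the population sd of the valid cells in the window; where it
    is zero (a locally flat layer contributes no heterogeneity signal) the
    z-score is 0 rather than nodata.

    With ``strict_circular=False`` the window degrades to the bounding
    square of the circle, which is cheaper for very large radii; the
    default keeps the exact circular footprint.
    """
    if spec is None:
        spec = NeighborhoodSpec(radius_px=200)
    r = spec.radius_px
    if strict_circular:
        stencil = circular_footprint(r).astype(float)
    else:
        stencil = np.ones((2 * r + 1, 2 * r + 1), dtype=float)

    valid = grid.valid.astype(float)
    # Z-scores are invariant to a global shift; centering on the global
    # mean keeps the windowed sum-of-squares well conditioned (a constant
    # layer becomes exact zeros even on the FFT path).
    center = float(np.mean(grid.values[grid.valid], dtype=float))
    vals = grid.masked(fill=np.nan) - center
    spread = float(np.nanmax(np.abs(vals))) if np.isfinite(vals).any() else 0.0
    vals = np.nan_to_num(vals, nan=0.0)
    n = _focal_sum(valid, stencil)
    s1 = _focal_sum(vals * valid, stencil)
    s2 = _focal_sum(vals * vals * valid, stencil)
    n = np.maximum(np.rint(n), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = s2 / n - mean * mean
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)

    raw = grid.masked(fill=np.nan) - center
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - mean) / sd
    # sd = 0 (a locally flat layer) yields z = 0; the threshold is scaled
    # to the data spread so round-off never masquerades as variation.
    flat = sd <= 1e-12 * max(spread, 1.0)
    z = np.where(flat, 0.0, z)
    mask = grid.nodata_mask | (n < 1)
    z[mask] = np.nan
    return grid.with_values(z, nodata_mask=mask)
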