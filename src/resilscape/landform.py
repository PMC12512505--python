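"""Landform classification from a digital elevation model.

Landforms -- summits, valleys, steep slopes, flats -- are discrete
topographic classes whose variety within a neighborhood proxies the
diversity of microclimates a site offers.  Cells are classified from
four terrain metrics:

* slope (degrees), from a 3x3 Horn plane fit;
* aspect (degrees clockwise from north, downslope direction), used only
  through an equator-facing / pole-facing split of steep slopes, since
  the facing controls solar radiation load;
* topographic position index (TPI): elevation minus the focal mean
  elevation, positive on ridges and negative in valleys;
* moisture accumulation index: ln((flow_accumulation + 1) / tan(slope)),
  high where D8 drainage converges on gentle ground.

The classification itself is an ordered rule cascade over these metrics,
shipped as a configurable taxonomy (10 classes by default) so the class
list and thresholds can be re-calibrated without touching code.  Landform
variety is the count of distinct classes within a circular window,
by default 5 px (~450 m on a 90 m grid).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from resilscape.raster_core import (
    Grid,
    NeighborhoodSpec,
    ensure_congruent,
    focal_apply,
)

__all__ = [
    "TerrainMetrics",
    "TaxonomyRule",
    "Taxonomy",
    "default_taxonomy",
    "load_taxonomy",
    "terrain_metrics",
    "classify_landforms",
    "landform_variety",
]

#: tan(0.57 deg) ~ 0.01 -- keeps the moisture index finite on flats,
#: standard wetness-index practice.
SLOPE_FLOOR_DEG = 0.57

# D8 neighbor scan order; ties in steepest descent break on the first
# entry, making flow routing deterministic.
_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class TerrainMetrics:
    """Per-cell terrain metrics on a shared grid.

    ``aspect`` is nodata-flagged wherever ``flat`` is True (aspect is
    undefined at zero slope).
    """

    slope: Grid  # degrees in [0, 90]
    aspect: Grid  # degrees in [0, 360), downslope azimuth
    flat: np.ndarray  # True where slope ~ 0 (aspect undefined)
    tpi: Grid  # m, signed
    moisture_index: Grid  # dimensionless
    equator_facing: np.ndarray  # True where a sloped cell faces the equator

    def layers(self) -> tuple[Grid, ...]:
        return (self.slope, self.aspect, self.tpi, self.moisture_index)


# ---------------------------------------------------------------------------
# terrain metrics
# ---------------------------------------------------------------------------


def _horn_gradients(dem: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Horn (1,2,1)-weighted gradients, in m per m of ground distance.

    gx is the eastward and gy the northward derivative.  Edges replicate;
    nodata neighbors take the center value so valid centers stay valid.
    """
    z = dem.masked(fill=np.nan)
    zp = np.pad(z, 1, mode="edge")
    center = zp[1:-1, 1:-1]
    win = {}
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            w = zp[1 + di : zp.shape[0] - 1 + di, 1 + dj : zp.shape[1] - 1 + dj]
            win[(di, dj)] = np.where(np.isnan(w), center, w)
    cs = dem.cell_size
    gx = (
        (win[(-1, 1)] + 2 * win[(0, 1)] + win[(1, 1)])
        - (win[(-1, -1)] + 2 * win[(0, -1)] + win[(1, -1)])
    ) / (8.0 * cs)
    # rows grow southward, so the northward derivative flips the row axis
    gy = (
        (win[(-1, -1)] + 2 * win[(-1, 0)] + win[(-1, 1)])
        - (win[(1, -1)] + 2 * win[(1, 0)] + win[(1, 1)])
    ) / (8.0 * cs)
    return gx, gy


def _d8_flow_accumulation(dem: Grid) -> np.ndarray:
    """Cells draining through each cell (upslope count, self excluded).

    Single-direction (D8) routing to the steepest downslope neighbor,
    ties broken by the fixed scan order; flats and pits do not route.
    """
    z = dem.masked(fill=np.nan)
    nrow, ncol = z.shape
    dist = np.array([np.hypot(di, dj) for di, dj in _D8])
    receiver = np.full((nrow, ncol), -1, dtype=np.int64)
    for i in range(nrow):
        for j in range(ncol):
            if np.isnan(z[i, j]):
                continue
            best_drop = 0.0
            best = -1
            for k, (di, dj) in enumerate(_D8):
                ii, jj = i + di, j + dj
                if 0 <= ii < nrow and 0 <= jj < ncol and not np.isnan(z[ii, jj]):
                    drop = (z[i, j] - z[ii, jj]) / dist[k]
                    if drop > best_drop:
                        best_drop = drop
                        best = ii * ncol + jj
            receiver[i, j] = best
    acc = np.zeros(nrow * ncol, dtype=np.int64)
    flat_z = z.ravel()
    order = np.argsort(-np.nan_to_num(flat_z, nan=-np.inf), kind="stable")
    recv = receiver.ravel()
    for idx in order:
        if np.isnan(flat_z[idx]) or recv[idx] < 0:
            continue
        acc[recv[idx]] += acc[idx] + 1
    return acc.reshape(nrow, ncol)


def terrain_metrics(
    dem: Grid,
    tpi_spec: NeighborhoodSpec | None = None,
    *,
    slope_floor_deg: float = SLOPE_FLOOR_DEG,
    flat_slope_deg: float = 1e-6,
) -> TerrainMetrics:
    """Compute slope, aspect, TPI and moisture accumulation from a DEM."""
    if tpi_spec is None:
        tpi_spec = NeighborhoodSpec(radius_px=5)
    vi, vj = np.nonzero(dem.valid)
    if len(vi) == 0 or np.ptp(vi) < 2 or np.ptp(vj) < 2:
        raise ValueError("DEM valid extent is smaller than 3x3")

    gx, gy = _horn_gradients(dem)
    slope_deg = np.degrees(np.arctan(np.hypot(gx, gy)))
    flat = slope_deg <= flat_slope_deg
    # downslope azimuth, clockwise from north
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect_vals = np.where(flat, np.nan, aspect)
    aspect_mask = dem.nodata_mask | flat

    tpi_mean = focal_apply(dem, tpi_spec, "mean")
    tpi_vals = dem.masked(fill=np.nan) - tpi_mean.masked(fill=np.nan)

    acc = _d8_flow_accumulation(dem)
    slope_rad = np.radians(np.maximum(slope_deg, slope_floor_deg))
    moisture = np.log((acc + 1.0) / np.tan(slope_rad))

    southern = dem.origin[1] < 0
    if southern:
        # equator is north: facing within 90 deg of azimuth 0
        eqf = (aspect_vals <= 90.0) | (aspect_vals >= 270.0)
    else:
        eqf = (aspect_vals > 90.0) & (aspect_vals < 270.0)
    eqf = np.where(np.isnan(aspect_vals), False, eqf).astype(bool)

    nod = dem.nodata_mask
    mk = lambda v, m=nod: dem.with_values(np.where(m, np.nan, v), nodata_mask=m)
    return TerrainMetrics(
        slope=mk(slope_deg),
        aspect=mk(aspect_vals, aspect_mask),
        flat=flat & dem.valid,
        tpi=mk(tpi_vals, tpi_mean.nodata_mask),
        moisture_index=mk(moisture),
        equator_facing=eqf,
    )


# ---------------------------------------------------------------------------
# taxonomy + classification
# ---------------------------------------------------------------------------

_OPS = {"<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge, "==": operator.eq}
_METRICS = ("slope", "tpi", "moisture", "equator_facing")


@dataclass(frozen=True)
class TaxonomyRule:
    code: int
    name: str
    when: tuple[tuple[str, str, float], ...] = ()

    def matches(self, fields: dict[str, np.ndarray]) -> np.ndarray:
        out = None
        for metric, op, threshold in self.when:
            cond = _OPS[op](fields[metric], threshold)
            out = cond if out is None else (out & cond)
        if out is None:
            return np.ones(next(iter(fields.values())).shape, dtype=bool)
        return out


@dataclass(frozen=True)
class Taxonomy:
    """Ordered first-match rule cascade; the final rule must be a catch-all
    so every valid cell receives exactly one code."""

    rules: tuple[TaxonomyRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("taxonomy has no rules")
        codes = [r.code for r in self.rules]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate landform codes in taxonomy: {codes}")
        if self.rules[-1].when:
            raise ValueError(
                "taxonomy rules are not exhaustive: the last rule must be an "
                "unconditional catch-all"
            )
        for r in self.rules:
            for metric, op, _ in r.when:
                if metric not in _METRICS:
                    raise ValueError(f"rule {r.code}: unknown metric {metric!r}")
                if op not in _OPS:
                    raise ValueError(f"rule {r.code}: unknown comparator {op!r}")

    @property
    def codes(self) -> list[int]:
        return [r.code for r in self.rules]


def default_taxonomy(
    *,
    cliff_deg: float = 40.0,
    steep_deg: float = 15.0,
    gentle_deg: float = 2.0,
    tpi_hi: float = 5.0,
    tpi_lo: float = -5.0,
    moist_hi: float = 6.0,
) -> Taxonomy:
    """Ten-class cascade over (slope, tpi, moisture, facing).

    Thresholds: slopes steeper than ``cliff_deg`` are cliffs; ``steep_deg``
    splits hillslopes from gentle ground and ``gentle_deg`` gentle ground
    from flats; |TPI| beyond ``tpi_hi``/``tpi_lo`` (m) marks ridges and
    valleys; a moisture index above ``moist_hi`` (roughly a 400-cell
    upslope area on gentle ground) marks wet positions.
    """
    r = TaxonomyRule
    return Taxonomy(
        rules=(
            r(6, "cliff", (("slope", ">", cliff_deg),)),
            r(10, "summit", (("tpi", ">", tpi_hi), ("slope", "<=", gentle_deg))),
            r(9, "ridge/hilltop", (("tpi", ">", tpi_hi),)),
            r(8, "moist valley", (("tpi", "<", tpi_lo), ("moisture", ">", moist_hi))),
            r(7, "valley/toeslope", (("tpi", "<", tpi_lo),)),
            r(4, "dry steep slope", (("slope", ">", steep_deg), ("equator_facing", ">=", 1.0))),
            r(5, "cool steep slope", (("slope", ">", steep_deg),)),
            r(3, "gentle slope", (("slope", ">", gentle_deg),)),
            r(2, "wet flat", (("moisture", ">", moist_hi),)),
            r(1, "flat plain"),
        )
    )


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load a taxonomy from YAML: a list of {code, name, when} mappings,
    where each ``when`` entry is [metric, comparator, threshold]."""
    raw = yaml.safe_load(Path(path).read_text())
    rules = tuple(
        TaxonomyRule(
            code=int(item["code"]),
            name=str(item["name"]),
            when=tuple((str(m), str(op), float(t)) for m, op, t in item.get("when", [])),
        )
        for item in raw
    )
    return Taxonomy(rules)


def classify_landforms(metrics: TerrainMetrics, taxonomy: Taxonomy | None = None) -> Grid:
    """Assign one landform code per valid cell by first-match over the cascade."""
    if taxonomy is None:
        taxonomy = default_taxonomy()
    ensure_congruent(metrics.slope, metrics.tpi, metrics.moisture_index)
    fields = {
        "slope": metrics.slope.masked(fill=np.nan),
        "tpi": metrics.tpi.masked(fill=np.nan),
        "moisture": metrics.moisture_index.masked(fill=np.nan),
        "equator_facing": metrics.equator_facing.astype(float),
    }
    base = metrics.slope
    mask = (
        metrics.slope.nodata_mask
        | metrics.tpi.nodata_mask
        | metrics.moisture_index.nodata_mask
    )
    codes = np.zeros(base.shape, dtype=np.int64)
    unassigned = ~mask
    with np.errstate(invalid="ignore"):
        for rule in taxonomy.rules:
            hit = rule.matches(fields) & unassigned
            codes[hit] = rule.code
            unassigned &= ~hit
    codes_f = codes.astype(float)
    codes_f[mask] = np.nan
    return base.with_values(codes_f, nodata_mask=mask)


def landform_variety(landforms: Grid, spec: NeighborhoodSpec | None = None) -> Grid:
    """Distinct landform codes within the circular window of each cell
    (>= 1 wherever the center is valid)."""
    if spec is None:
        spec = NeighborhoodSpec(radius_px=5)
    return focal_apply(landforms, spec, "count_distinct")
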