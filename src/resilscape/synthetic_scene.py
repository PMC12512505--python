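"""Synthetic input scenes for the resilience pipeline.

Generates congruent stacks (DEM, wetlands, soils, land cover, water,
zones) with controlled structure so every stage and the end-to-end run
can be exercised without real datasets.  The layers emulate the
*structure* of the pipeline's real-world inputs -- 90 m cells, terrain
with flats, ridges and valleys, wetlands clustered on low ground
(floodplain-style), patchy soil mosaics, and land-cover mosaics spanning
the natural-to-urban resistance gradient with linear features (roads and
a river of configurable width) -- not the statistics of any particular
region.

Everything is deterministic under (config, seed): the same scene config
always produces bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from resilscape.raster_core import Grid, ensure_congruent

__all__ = ["SceneConfig", "make_scene", "make_gradient_scene"]

# land-cover codes of the default resistance table
NATURAL_FOREST, NATURAL_WETLAND, NATURAL_GRASSLAND = 1, 2, 3
SECONDARY, PASTURE, CROPLAND, MINING, ROAD, URBAN = 4, 5, 6, 7, 8, 9
RIVER_NARROW, RIVER_MEDIUM, RIVER_WIDE = 20, 21, 22


@dataclass(frozen=True)
class SceneConfig:
    """Recipe for one synthetic scene.

    ``lulc_recipe`` lists (class code, target fraction, patch scale in
    cells); the remaining fraction is natural-forest matrix.  Realized
    class fractions track the targets to within about two percentage
    points at 256x256.  ``river_width_px`` = 0 disables the river.
    """

    shape: tuple[int, int] = (128, 128)
    cell_size: float = 90.0
    seed: int = 0
    terrain: str = "fractal"  # plane | cone | ridge_valley | fractal
    hurst: float = 0.8
    relief_m: float = 300.0
    origin: tuple[float, float] = (0.0, -1_000_000.0)  # southern hemisphere
    wetland_fraction: float = 0.05
    wetland_cluster_px: float = 4.0
    n_soil_types: int = 4
    soil_patch_px: float = 24.0
    lulc_recipe: tuple[tuple[int, float, float], ...] = (
        (PASTURE, 0.20, 16.0),
        (CROPLAND, 0.15, 16.0),
        (URBAN, 0.05, 10.0),
    )
    n_roads: int = 1
    river_width_px: int = 2
    n_zones: int = 2

    def __post_init__(self) -> None:
        frac = sum(f for _, f, _ in self.lulc_recipe)
        if frac > 1.0 + 1e-9:
            raise ValueError(f"lulc_recipe fractions sum to {frac} > 1")
        if self.terrain not in ("plane", "cone", "ridge_valley", "fractal"):
            raise ValueError(f"unknown terrain recipe {self.terrain!r}")
        if not (0.0 <= self.wetland_fraction <= 1.0):
            raise ValueError("wetland_fraction must be in [0, 1]")
        if self.n_soil_types < 1 or self.n_zones < 1:
            raise ValueError("n_soil_types and n_zones must be >= 1")


# ---------------------------------------------------------------------------
# terrain recipes
# ---------------------------------------------------------------------------


def _terrain(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    nr, nc = cfg.shape
    ii, jj = np.mgrid[0:nr, 0:nc].astype(float)
    if cfg.terrain == "plane":
        return np.zeros((nr, nc))
    if cfg.terrain == "cone":
        # analytic cone: radially symmetric slope, apex at the center
        ci, cj = (nr - 1) / 2.0, (nc - 1) / 2.0
        r = np.hypot(ii - ci, jj - cj)
        return np.maximum(0.0, cfg.relief_m * (1.0 - r / (min(nr, nc) / 2.5)))
    if cfg.terrain == "ridge_valley":
        # parallel ridges and valleys with a gentle along-axis fall so
        # D8 drainage runs down the valley floors
        wavelength = max(nc / 4.0, 8.0)
        across = 0.5 * (1.0 + np.sin(2.0 * np.pi * jj / wavelength))
        along = 0.05 * (nr - ii) / nr
        return cfg.relief_m * (across + along)
    # fractal: spectral synthesis with power-law falloff (Hurst exponent)
    white = rng.standard_normal((nr, nc))
    spec = np.fft.fft2(white)
    fy = np.fft.fftfreq(nr)[:, None]
    fx = np.fft.fftfreq(nc)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf
    spec *= f ** (-(1.0 + cfg.hurst))
    rough = np.real(np.fft.ifft2(spec))
    rough -= rough.min()
    peak = rough.max()
    if peak > 0:
        rough /= peak
    return cfg.relief_m * rough


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------


def _voronoi_mosaic(
    shape: tuple[int, int],
    class_of_seed: np.ndarray,
    seed_rows: np.ndarray,
    seed_cols: np.ndarray,
) -> np.ndarray:
    """Nearest-seed-point assignment: contiguous deterministic patches."""
    nr, nc = shape
    ii, jj = np.mgrid[0:nr, 0:nc]
    d2 = (ii[..., None] - seed_rows) ** 2 + (jj[..., None] - seed_cols) ** 2
    nearest = np.argmin(d2, axis=-1)
    return class_of_seed[nearest]


def _largest_remainder_counts(fracs: np.ndarray, n: int) -> np.ndarray:
    raw = fracs * n
    out = np.floor(raw).astype(int)
    rem = n - out.sum()
    order = np.argsort(-(raw - out), kind="stable")
    for k in range(rem):
        out[order[k % len(out)]] += 1
    return out


def _lulc(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    nr, nc = cfg.shape
    recipe = list(cfg.lulc_recipe)
    natural_frac = 1.0 - sum(f for _, f, _ in recipe)
    recipe.append((NATURAL_FOREST, natural_frac, 16.0))
    # one Voronoi seed per (patch scale)^2 cells, allocated to classes by
    # largest remainder so realized fractions track the recipe
    mean_scale = float(np.mean([s for _, _, s in recipe]))
    n_seeds = max(len(recipe), int(round(nr * nc / mean_scale**2)))
    fracs = np.array([f for _, f, _ in recipe])
    fracs = fracs / fracs.sum() if fracs.sum() > 0 else np.full(len(recipe), 1.0 / len(recipe))
    counts = _largest_remainder_counts(fracs, n_seeds)
    class_of_seed = np.repeat([c for c, _, _ in recipe], counts)
    rng.shuffle(class_of_seed)
    rows = rng.integers(0, nr, size=n_seeds)
    cols = rng.integers(0, nc, size=n_seeds)
    return _voronoi_mosaic((nr, nc), class_of_seed, rows, cols)


def _wetlands(cfg: SceneConfig, dem: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Clustered wetland patches concentrated on low ground.

    A smoothed noise field plus a bonus for low DEM rank is thresholded
    at the target fraction quantile: clusters come from the smoothing,
    the floodplain bias from the rank term.
    """
    nr, nc = cfg.shape
    if cfg.wetland_fraction <= 0:
        return np.zeros((nr, nc), dtype=np.int64)
    if cfg.wetland_fraction >= 1:
        return np.ones((nr, nc), dtype=np.int64)
    noise = ndimage.gaussian_filter(
        rng.standard_normal((nr, nc)), sigma=cfg.wetland_cluster_px, mode="reflect"
    )
    noise = (noise - noise.mean()) / (noise.std() or 1.0)
    order = np.argsort(np.argsort(dem.ravel(), kind="stable"), kind="stable")
    dem_rank = order.reshape(nr, nc) / max(nr * nc - 1, 1)
    lowness = 1.0 / (1.0 + np.exp(8.0 * (dem_rank - 0.35)))  # logistic of rank
    score = noise + 2.0 * lowness
    cut = np.quantile(score, 1.0 - cfg.wetland_fraction)
    return (score > cut).astype(np.int64)


def _river_path(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Meandering north-south river of the configured width; 0/1 mask."""
    nr, nc = cfg.shape
    mask = np.zeros((nr, nc), dtype=bool)
    if cfg.river_width_px <= 0:
        return mask
    center = nc * (0.35 + 0.3 * rng.random())
    amp = nc * 0.08
    phase = rng.random() * 2 * np.pi
    cols = center + amp * np.sin(2 * np.pi * np.arange(nr) / max(nr / 2.0, 8.0) + phase)
    half = cfg.river_width_px / 2.0
    for i in range(nr):
        lo = int(np.floor(cols[i] - half + 0.5))
        hi = lo + cfg.river_width_px
        mask[i, max(lo, 0) : min(hi, nc)] = True
    return mask


def _river_code(width_px: int) -> int:
    if width_px <= 1:
        return RIVER_NARROW
    if width_px <= 3:
        return RIVER_MEDIUM
    return RIVER_WIDE


def make_scene(config: SceneConfig) -> dict[str, Grid]:
    """Generate the full congruent input stack for one scene.

    Returns layers ``dem`` (m), ``wetlands`` (0/1), ``soils`` (codes
    1..n_soil_types), ``lulc`` (codes of the default resistance table),
    ``water`` (0/1: the river), and ``zones`` (vertical bands 1..n_zones).
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.shape
    geo = dict(cell_size=config.cell_size, origin=config.origin, crs_tag="synthetic")

    dem = _terrain(config, rng)
    wet = _wetlands(config, dem, rng)
    # soils: nearest-seed mosaic with each type appearing at least once
    n_soil_seeds = max(config.n_soil_types, int(round(nr * nc / config.soil_patch_px**2)))
    soil_types = np.concatenate(
        [
            np.arange(1, config.n_soil_types + 1),
            rng.integers(1, config.n_soil_types + 1, size=n_soil_seeds - config.n_soil_types),
        ]
    )
    soils = _voronoi_mosaic(
        (nr, nc),
        soil_types,
        rng.integers(0, nr, size=n_soil_seeds),
        rng.integers(0, nc, size=n_soil_seeds),
    )
    lulc = _lulc(config, rng)
    # wetland cells present as natural wetland cover unless human-converted
    natural = np.isin(lulc, (NATURAL_FOREST, NATURAL_GRASSLAND))
    lulc = np.where((wet == 1) & natural, NATURAL_WETLAND, lulc)
    # linear features override the mosaic: roads then the river on top
    for k in range(config.n_roads):
        row = int((k + 1) * nr / (config.n_roads + 1))
        lulc[row, :] = ROAD
    river = _river_path(config, rng)
    lulc = np.where(river, _river_code(config.river_width_px), lulc)
    water = river.astype(np.int64)
    zones = 1 + (np.arange(nc)[None, :] * config.n_zones) // nc
    zones = np.broadcast_to(zones, (nr, nc)).copy()

    stack = {
        "dem": Grid(dem.astype(float), **geo),
        "wetlands": Grid(wet.astype(float), **geo),
        "soils": Grid(soils.astype(float), **geo),
        "lulc": Grid(lulc.astype(float), **geo),
        "water": Grid(water.astype(float), **geo),
        "zones": Grid(zones.astype(float), **geo),
    }
    ensure_congruent(*stack.values())
    return stack


def make_gradient_scene(
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    cell_size: float = 90.0,
) -> dict[str, Grid]:
    """Natural-vs-anthropic contrast scene for end-to-end checks.

    Both halves share the same rough (fractal) terrain, so landscape
    heterogeneity is statistically similar left and right; land cover is
    natural on the left half and a cropland/pasture/urban mosaic on the
    right, so connectedness differs sharply.  Zone 1 is the left
    (natural) half, zone 2 the right (anthropic) half.
    """
    nr, nc = shape
    base = SceneConfig(
        shape=shape,
        cell_size=cell_size,
        seed=seed,
        terrain="fractal",
        wetland_fraction=0.05,
        n_soil_types=4,
        lulc_recipe=(),
        n_roads=0,
        river_width_px=0,
        n_zones=2,
    )
    stack = make_scene(base)
    rng = np.random.default_rng(seed + 1)
    anthropic = _lulc(
        SceneConfig(
            shape=shape,
            seed=seed,
            lulc_recipe=(
                (CROPLAND, 0.40, 12.0),
                (PASTURE, 0.30, 12.0),
                (URBAN, 0.15, 8.0),
                (SECONDARY, 0.10, 12.0),
            ),
        ),
        rng,
    )
    lulc = stack["lulc"].values.copy()
    half = nc // 2
    lulc[:, half:] = anthropic[:, half:]
    stack["lulc"] = stack["lulc"].with_values(lulc)
    return stack
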