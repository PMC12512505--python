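"""Local connectedness from a land-cover resistance surface.

Land-use/land-cover classes impose different resistance to the movement
of terrestrial organisms: natural cover is the most permeable (lowest
resistance), intensively used and urban areas the least, with a gradient
between the extremes.  Rivers and lakes resist crossing in proportion to
their width, and linear infrastructure (roads, transmission lines)
overrides the underlying cover with its own higher resistance.

Local connectedness is the reciprocal of the kernel-weighted mean
resistance within a circular moving window (23 px, ~2070 m on a 90 m
grid), under a linear-decay kernel that gives nearby cells more
influence than distant ones.  With resistances constrained >= 1,
connectedness lies in (0, 1]; higher means more permeable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from resilscape.raster_core import (
    Grid,
    Kernel,
    NeighborhoodSpec,
    focal_apply,
)

__all__ = [
    "ResistanceTable",
    "default_resistance_table",
    "map_resistance",
    "linear_decay_kernel",
    "local_connectedness",
]

#: Default class codes of the synthetic land-cover recipe.  Stand-in values
#: spanning the natural (1) to urban (100) resistance gradient, with river
#: resistance growing with width class; fully user-overridable.
DEFAULT_ENTRIES: dict[int, tuple[str, float]] = {
    1: ("natural forest", 1.0),
    2: ("natural wetland", 1.0),
    3: ("natural grassland", 1.0),
    4: ("secondary/managed vegetation", 5.0),
    5: ("pasture", 20.0),
    6: ("annual cropland", 40.0),
    7: ("mining/bare", 70.0),
    8: ("road", 80.0),
    9: ("urban", 100.0),
    20: ("river narrow", 2.0),
    21: ("river medium", 30.0),
    22: ("river wide", 90.0),
}


@dataclass(frozen=True)
class ResistanceTable:
    """Land-cover code -> resistance (dimensionless, >= 1)."""

    entries: dict[int, float]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, r in self.entries.items():
            if not r >= 1.0:
                raise ValueError(
                    f"resistance for code {code} must be >= 1, got {r}"
                )

    @property
    def r_min(self) -> float:
        return min(self.entries.values())

    @property
    def r_max(self) -> float:
        return max(self.entries.values())

    def with_entry(self, code: int, resistance: float) -> "ResistanceTable":
        entries = dict(self.entries)
        entries[code] = resistance
        return ResistanceTable(entries, dict(self.labels))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResistanceTable":
        """Read columns (code, label, resistance) from a CSV file."""
        entries: dict[int, float] = {}
        labels: dict[int, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                code = int(row["code"])
                entries[code] = float(row["resistance"])
                labels[code] = row.get("label", "")
        return cls(entries, labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResistanceTable":
        raw = yaml.safe_load(Path(path).read_text())
        entries = {int(k): float(v) for k, v in raw.items()}
        return cls(entries)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "label", "resistance"])
            for code in sorted(self.entries):
                w.writerow([code, self.labels.get(code, ""), self.entries[code]])
        return path


def default_resistance_table() -> ResistanceTable:
    return ResistanceTable(
        entries={c: r for c, (_, r) in DEFAULT_ENTRIES.items()},
        labels={c: name for c, (name, _) in DEFAULT_ENTRIES.items()},
    )


def map_resistance(lulc: Grid, table: ResistanceTable | None = None) -> Grid:
    """Per-cell resistance lookup from the land-cover raster.

    Every code present in the raster must have a table entry; unmapped
    codes raise an error naming them rather than taking a silent default.
    """
    if table is None:
        table = default_resistance_table()
    codes = np.unique(lulc.values[lulc.valid]).astype(int)
    missing = sorted(int(c) for c in codes if int(c) not in table.entries)
    if missing:
        raise KeyError(
            f"land-cover codes with no resistance entry: {missing}"
        )
    out = np.full(lulc.shape, np.nan)
    vals = lulc.values
    for code in codes:
        out[(vals == code) & lulc.valid] = table.entries[int(code)]
    return lulc.with_values(out, nodata_mask=lulc.nodata_mask)


def linear_decay_kernel(radius_px: int = 23) -> np.ndarray:
    """Linear-decay weight stencil for the connectedness window.

    weight(d) is proportional to 1 - d/(radius+1) for center-to-center
    distance d <= radius, so the decay is strictly positive at the rim
    and reaches zero just beyond it; weights are normalized to sum to 1
    over the full stencil.
    """
    spec = NeighborhoodSpec(radius_px=radius_px, kernel=Kernel.LINEAR_DECAY)
    w = spec.weights()
    return w / w.sum()


def local_connectedness(
    resistance: Grid,
    radius_px: int = 23,
    *,
    inverse_mode: str = "reciprocal",
) -> Grid:
    """Connectedness = inverse of the kernel-weighted mean resistance.

    The weighted mean uses the linear-decay stencil, with weights
    renormalized over the valid in-bounds cells of each window so edge
    cells stay true means.  ``inverse_mode`` selects the reading of
    "inverse": ``reciprocal`` (default) is 1/weighted_mean, giving values
    in [1/R_max, 1/R_min]; ``complement`` linearly flips the weighted
    mean onto [0, 1] over the observed resistance span.
    """
    vals = resistance.values[resistance.valid]
    if vals.size and np.nanmin(vals) < 1.0:
        raise ValueError("resistance must be >= 1 everywhere valid")
    spec = NeighborhoodSpec(radius_px=radius_px, kernel=Kernel.LINEAR_DECAY)
    wmean = focal_apply(resistance, spec, "weighted_mean")
    wm = wmean.masked(fill=np.nan)
    if inverse_mode == "reciprocal":
        out = 1.0 / wm
    elif inverse_mode == "complement":
        lo = float(np.nanmin(wm)) if np.isfinite(wm).any() else 0.0
        hi = float(np.nanmax(wm)) if np.isfinite(wm).any() else 1.0
        span = hi - lo
        out = (hi - wm) / span if span > 0 else np.ones_like(wm)
    else:
        raise ValueError(
            f"inverse_mode must be 'reciprocal' or 'complement', got {inverse_mode!r}"
        )
    out[wmean.nodata_mask] = np.nan
    return wmean.with_values(out, nodata_mask=wmean.nodata_mask)
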