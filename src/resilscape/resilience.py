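"""Bivariate quartile classification into resilience classes and quadrants.

Landscape resilience overlays the heterogeneity and connectedness layers
on a bivariate quartile scale.  Each layer is cut at its empirical 25th,
50th and 75th percentiles (computed once over all valid pixels of the
full extent, so no per-zone standardization is needed); a cell's class
is the two-digit code 11-44 whose first digit is the connectedness
quartile and second digit the heterogeneity quartile.  The 16 classes
group into four quadrants:

* Q1 (11, 12, 21, 22) -- low connectedness, low heterogeneity (lowest
  resilience);
* Q2 (13, 14, 23, 24) -- low connectedness, high heterogeneity
  (restoration potential);
* Q3 (31, 32, 41, 42) -- high connectedness, low heterogeneity
  (corridor value);
* Q4 (33, 34, 43, 44) -- high both (highest resilience).

Water bodies are masked from the final map (they receive no resilience
class), and zonal summaries report the percent of area per class and per
quadrant, both within each zone and across the whole extent, with
largest-remainder rounding so printed totals hit 100.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from resilscape.raster_core import Grid, ensure_congruent

__all__ = [
    "QuartileBreaks",
    "QUADRANTS",
    "quadrant_of",
    "quartile_breaks",
    "bivariate_classify",
    "mask_water",
    "round_percentages",
    "zonal_summary",
]

#: Quadrant -> class codes (first digit = connectedness quartile,
#: second digit = heterogeneity quartile).
QUADRANTS: dict[str, tuple[int, ...]] = {
    "Q1": (11, 12, 21, 22),
    "Q2": (13, 14, 23, 24),
    "Q3": (31, 32, 41, 42),
    "Q4": (33, 34, 43, 44),
}

#: Display palette for class maps (Q1 gray, Q2 blue, Q3 yellow, Q4 green).
QUADRANT_COLORS = {"Q1": "#808080", "Q2": "#2166ac", "Q3": "#ffd92f", "Q4": "#1a9850"}

_CODE_TO_QUADRANT = {code: q for q, codes in QUADRANTS.items() for code in codes}


def quadrant_of(code: int) -> str:
    """Quadrant label for a bivariate class code 11-44."""
    try:
        return _CODE_TO_QUADRANT[int(code)]
    except KeyError:
        raise ValueError(f"not a bivariate class code: {code}") from None


@dataclass(frozen=True)
class QuartileBreaks:
    """25/50/75 percentile breaks of one layer over the full extent."""

    q25: float
    q50: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError(f"breaks must be ordered, got {self}")

    def bin(self, values: np.ndarray) -> np.ndarray:
        """Quartile bin 1-4 per value; upper edges inclusive
        (value <= q25 -> 1, <= q50 -> 2, <= q75 -> 3, else 4)."""
        v = np.asarray(values, dtype=float)
        out = np.full(v.shape, 4, dtype=np.int64)
        out[v <= self.q75] = 3
        out[v <= self.q50] = 2
        out[v <= self.q25] = 1
        return out


def quartile_breaks(grid: Grid, *, method: str = "linear") -> QuartileBreaks:
    """Empirical quartile breaks of the valid cells.

    ``method`` is passed to numpy's percentile machinery; the default is
    linear interpolation (``"lower"`` etc. give nearest-rank variants).
    """
    vals = grid.values[grid.valid].astype(float)
    if vals.size < 4:
        raise ValueError(f"need >= 4 valid cells for quartiles, got {vals.size}")
    q25, q50, q75 = np.percentile(vals, [25.0, 50.0, 75.0], method=method)
    return QuartileBreaks(float(q25), float(q50), float(q75))


def bivariate_classify(
    heterogeneity: Grid,
    connectedness: Grid,
    hb: QuartileBreaks | None = None,
    cb: QuartileBreaks | None = None,
) -> Grid:
    """Two-digit class code per cell: 10*connectedness_bin + heterogeneity_bin.

    Breaks default to the layers' own full-extent quartiles.  Output is
    nodata wherever either input is nodata.
    """
    ensure_congruent(heterogeneity, connectedness)
    if hb is None:
        hb = quartile_breaks(heterogeneity)
    if cb is None:
        cb = quartile_breaks(connectedness)
    code = 10 * cb.bin(connectedness.values) + hb.bin(heterogeneity.values)
    mask = heterogeneity.nodata_mask | connectedness.nodata_mask
    out = code.astype(float)
    out[mask] = np.nan
    return heterogeneity.with_values(out, nodata_mask=mask)


def mask_water(classes: Grid, water: Grid) -> Grid:
    """Remove water bodies from the class map (they stay unclassified)."""
    ensure_congruent(classes, water)
    wet = (water.values == 1) & water.valid
    mask = classes.nodata_mask | wet
    out = classes.masked(fill=np.nan)
    out[mask] = np.nan
    return classes.with_values(out, nodata_mask=mask)


def round_percentages(raw: np.ndarray, total: float = 100.0, decimals: int = 1) -> np.ndarray:
    """Largest-remainder rounding: round to ``decimals`` places so the
    printed values sum exactly to ``total`` (assumes raw sums to total)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw
    scale = 10.0**decimals
    scaled = raw * scale / 1.0
    floors = np.floor(scaled)
    shortfall = int(round(total * scale - floors.sum()))
    order = np.argsort(-(scaled - floors), kind="stable")
    out = floors.copy()
    for k in range(shortfall):
        out[order[k % raw.size]] += 1
    return out / scale


def zonal_summary(classes: Grid, zones: Grid) -> pd.DataFrame:
    """Percent-area accounting of classes and quadrants per zone.

    Returns one row per (zone, level, code) with columns ``zone``,
    ``level`` ('class' or 'quadrant'), ``code``, ``count``,
    ``pct_within`` (percent of the zone's classified cells) and
    ``pct_across`` (percent of all classified cells).  Both percentage
    columns use largest-remainder rounding to one decimal, so within-zone
    percents sum to 100.0 per zone and across-extent percents sum to
    100.0 over the whole level.  Zones without classified cells appear
    with zero counts and NaN (undefined) within-zone percents.
    """
    ensure_congruent(classes, zones)
    both = classes.valid & zones.valid
    total = int(both.sum())
    zone_ids = np.unique(zones.values[zones.valid]).astype(int)

    rows: list[dict] = []
    for level, keys in (
        ("class", [c for codes in QUADRANTS.values() for c in codes]),
        ("quadrant", list(QUADRANTS)),
    ):
        keys = sorted(keys, key=str)
        counts = np.zeros((len(zone_ids), len(keys)), dtype=np.int64)
        for zi, zid in enumerate(zone_ids):
            in_zone = both & (zones.values == zid)
            vals = classes.values[in_zone].astype(int)
            if level == "class":
                for ki, code in enumerate(keys):
                    counts[zi, ki] = int((vals == code).sum())
            else:
                quads = np.array([_CODE_TO_QUADRANT[v] for v in vals]) if vals.size else np.array([])
                for ki, q in enumerate(keys):
                    counts[zi, ki] = int((quads == q).sum()) if vals.size else 0
        # within-zone percents: rounded per zone
        pct_within = np.full(counts.shape, np.nan)
        for zi in range(len(zone_ids)):
            zone_total = counts[zi].sum()
            if zone_total > 0:
                pct_within[zi] = round_percentages(100.0 * counts[zi] / zone_total)
        # across-extent percents: rounded over the whole level at once
        if total > 0:
            pct_across = round_percentages(100.0 * counts.ravel() / total).reshape(
                counts.shape
            )
        else:
            pct_across = np.full(counts.shape, np.nan)
        for zi, zid in enumerate(zone_ids):
            for ki, key in enumerate(keys):
                rows.append(
                    {
                        "zone": int(zid),
                        "level": level,
                        "code": key,
                        "count": int(counts[zi, ki]),
                        "pct_within": pct_within[zi, ki],
                        "pct_across": pct_across[zi, ki],
                    }
                )
    return pd.DataFrame(rows, columns=["zone", "level", "code", "count", "pct_within", "pct_across"])
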