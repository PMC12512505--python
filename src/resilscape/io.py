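"""Raster and table I/O.

Rasters are stored as Esri ASCII grids (.asc): a six-line header
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) followed by the
value matrix, north row first.  The format is plain text, carries the
georeference the pipeline needs, and round-trips through any GIS.  The
crs tag travels in an optional JSON sidecar (<name>.asc.json).

All layers loaded for one run must share shape, cell size, origin and
crs; `read_stack` validates this on load and fails fast on mismatch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from resilscape.raster_core import Grid, ensure_congruent

__all__ = ["read_ascii_grid", "write_ascii_grid", "read_stack", "write_stack"]

_NODATA_DEFAULT = -9999.0


def write_ascii_grid(grid: Grid, path: str | Path, *, fmt: str = "%.8g") -> Path:
    """Write a grid as an Esri ASCII raster plus a JSON georeference sidecar."""
    path = Path(path)
    nrows, ncols = grid.shape
    x_ul, y_ul = grid.origin
    yll = y_ul - nrows * grid.cell_size
    vals = np.array(grid.values, dtype=float)
    vals[grid.nodata_mask] = _NODATA_DEFAULT
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x_ul!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA_DEFAULT!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    sidecar = {"crs_tag": grid.crs_tag}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))
    return path


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an Esri ASCII raster (and its sidecar, if present) into a Grid."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if vals.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {vals.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", _NODATA_DEFAULT)
    mask = vals == nodata
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    crs_tag = "local"
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        crs_tag = json.loads(sidecar.read_text()).get("crs_tag", "local")
    out = vals.copy()
    out[mask] = np.nan
    return Grid(out, cell_size=cell, origin=origin, crs_tag=crs_tag, nodata_mask=mask)


def write_stack(stack: dict[str, Grid], directory: str | Path) -> dict[str, Path]:
    """Write every layer of a congruent stack as <name>.asc under directory."""
    ensure_congruent(*stack.values())
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return {
        name: write_ascii_grid(grid, directory / f"{name}.asc")
        for name, grid in stack.items()
    }


def read_stack(directory: str | Path, names: list[str] | None = None) -> dict[str, Grid]:
    """Read <name>.asc layers from a directory and validate congruence."""
    directory = Path(directory)
    if names is None:
        names = sorted(p.stem for p in directory.glob("*.asc"))
    stack = {name: read_ascii_grid(directory / f"{name}.asc") for name in names}
    ensure_congruent(*stack.values())
    return stack
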