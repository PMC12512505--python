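import numpy as np
import pytest

from resilscape.raster_core import Grid


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_grid(values, *, mask=None, cell_size=90.0, origin=(0.0, -1e6)):
    return Grid(
        np.asarray(values, dtype=float),
        cell_size=cell_size,
        origin=origin,
        nodata_mask=mask,
    )


@pytest.fixture
def random_grid_with_holes(rng):
    """16x16 continuous grid with ~10% nodata, for focal-statistic checks."""
    vals = rng.normal(100.0, 15.0, size=(16, 16))
    mask = rng.random((16, 16)) < 0.10
    return make_grid(vals, mask=mask)


@pytest.fixture
def cone_dem():
    """Radially symmetric cone (radius 25 cells, ~15.4 deg flank) with a
    surrounding plain, apex at the center of a 61x61 grid."""
    n = 61
    ii, jj = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    r = np.hypot(ii - c, jj - c)
    dem = np.maximum(0.0, 620.0 * (1.0 - r / 25.0))
    return make_grid(dem)


@pytest.fixture
def valley_dem():
    """V-shaped valley running north-south with a gentle southward fall."""
    n = 15
    ii, jj = np.mgrid[0:n, 0:n].astype(float)
    axis = (n - 1) / 2
    dem = 40.0 * np.abs(jj - axis) + 2.0 * (n - 1 - ii)
    return make_grid(dem)
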