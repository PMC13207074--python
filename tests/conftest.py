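import datetime as dt

import numpy as np
import pytest

from rsei.grids import BAND_INDEX, BAND_NAMES, AnnualComposite, GeoGrid


@pytest.fixture
def small_grid():
    return GeoGrid(4, 5, 0.005, -36.0, -9.3)


def make_composite(band_values, lst=25.0, grid=None, year=2001):
    """Build an AnnualComposite with uniform band values.

    ``band_values`` maps band names to scalars or (rows, cols) arrays;
    unspecified bands default to 0.1.
    """
    grid = grid or GeoGrid(3, 3, 0.005, -36.0, -9.3)
    bands = np.full((len(BAND_NAMES),) + grid.shape, 0.1)
    for name, value in band_values.items():
        bands[BAND_INDEX[name]] = value
    lst_arr = np.full(grid.shape, float(lst)) if np.isscalar(lst) else np.asarray(lst)
    return AnnualComposite(year, grid, bands, lst_arr)


@pytest.fixture
def composite_factory():
    return make_composite


def a_date(year=2001, month=1, day=15):
    return dt.date(year, month, day)
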