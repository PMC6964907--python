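import numpy as np
import pandas as pd
import pytest

from paleoenm.data_io import BREEDING, BioclimStack, N_BIOCLIM, OccurrenceSet
from paleoenm.geometry import GridGeometry


@pytest.fixture
def small_grid() -> GridGeometry:
    return GridGeometry(xll=-120.0, yll=30.0, cellsize=0.5, n_rows=20, n_cols=30)


@pytest.fixture
def flat_stack(small_grid) -> BioclimStack:
    """A stack whose layer j is the plane j + 0.1*row + 0.05*col (no noise)."""
    rows = np.arange(small_grid.n_rows)[:, None]
    cols = np.arange(small_grid.n_cols)[None, :]
    values = np.stack([j + 0.1 * rows + 0.05 * cols for j in range(N_BIOCLIM)]).astype(float)
    return BioclimStack(small_grid, values, np.ones((small_grid.n_rows, small_grid.n_cols), bool), "present")


def make_occurrences(lons, lats, species="sp", season=BREEDING) -> OccurrenceSet:
    df = pd.DataFrame({"lon": lons, "lat": lats, "source": "test"})
    return OccurrenceSet(species, season, df)


@pytest.fixture
def occ_factory():
    return make_occurrences
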