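import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pfe.geo_grid import (
    AreaOfInfluence,
    CellValues,
    Grid,
    GridCell,
    PointObservations,
    build_grid,
)


def make_points(xy, values, source="test"):
    xy = np.asarray(xy, dtype=float)
    return PointObservations(
        pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "value": values}), source=source
    )


def make_cells(mapping, units=""):
    return CellValues(values=pd.Series(mapping, dtype=float).sort_index(), units=units)


@pytest.fixture
def square_aoi():
    """A 100 km x 100 km square area of influence anchored at the origin."""
    return AreaOfInfluence(
        polygon=box(0.0, 0.0, 100_000.0, 100_000.0), seaward_buffer_km=75.0
    )


@pytest.fixture
def small_grid(square_aoi) -> Grid:
    """2 x 2 grid of 50 km (2500 km2) cells covering the square AoI."""
    return build_grid(square_aoi, cell_area_km2=2500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
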