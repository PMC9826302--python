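import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import box

from climoccur import (GridDefinition, PolygonLayer, Raster,
                       SyntheticScenario, gen_occurrences)

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def dataset():
    """One default synthetic scenario (function-scoped: the cleaning pipeline
    mutates records in place)."""
    return gen_occurrences(SyntheticScenario(seed=7))


@pytest.fixture
def square_layers():
    """Two adjacent 10°x10° 'botanical countries' sharing an edge at lon 10."""
    tdwg = PolygonLayer([("SPA", box(0, 0, 10, 10)), ("FRA", box(10, 0, 20, 10))])
    iso = PolygonLayer([("ES", box(0, 0, 10, 10)), ("FR", box(10, 0, 20, 10))])
    return tdwg, iso


@pytest.fixture
def island_template():
    """A land template whose single data cell is an island at (10.05, 20.05)."""
    grid = GridDefinition(xmin=10.0, ymin=20.0, cellsize=0.1, ncols=5, nrows=5)
    values = np.full((5, 5), np.nan)
    values[4, 0] = 1.0  # bottom-left cell, center (10.05, 20.05)
    return Raster(grid, values)
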