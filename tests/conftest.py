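import numpy as np
import pytest

from nichetrack.grids import GridSpec, PeriodGrid, PeriodIndex


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def field_from(grid: GridSpec, fn, period=PeriodIndex(1954, 1958), kind="") -> PeriodGrid:
    """Build a PeriodGrid from a function of (lat, lon) arrays."""
    glat, glon = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    return PeriodGrid(grid=grid, values=np.asarray(fn(glat, glon), dtype=float),
                      period=period, kind=kind)
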