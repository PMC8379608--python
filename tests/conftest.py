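import numpy as np
import pytest

from gelget import (
    DoseResponse,
    GelGeometry,
    GelMedium,
    PlasmidSpec,
    standard_grid,
)


@pytest.fixture
def medium():
    return GelMedium()


@pytest.fixture
def plasmid():
    return PlasmidSpec()


@pytest.fixture
def geometry():
    return GelGeometry()


@pytest.fixture
def dr():
    return DoseResponse(K=1.0)


@pytest.fixture
def grid(geometry):
    return standard_grid(geometry)


@pytest.fixture
def gaussian_profile(grid):
    """Compact interior bump, well away from both gel faces."""
    from gelget import ConcentrationProfile

    c = 50.0 * np.exp(-0.5 * ((grid - 300.0) / 40.0) ** 2)
    return ConcentrationProfile(grid, c)
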