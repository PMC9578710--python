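import numpy as np
import pytest

from hipposhuttle.model import DEFAULT_PARAMS, build_topology
from hipposhuttle.synth import single_cell_geometry


@pytest.fixture(scope="session")
def alt_net():
    return build_topology("alternative")


@pytest.fixture(scope="session")
def can_net():
    return build_topology("canonical")


@pytest.fixture(scope="session")
def geo64():
    """64x64 single-cell domain at the live-cell pixel size."""
    return single_cell_geometry(
        size=64, pixel_size=1.24, cell_radius_um=30.0, nucleus_radius_um=12.0
    )


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS
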