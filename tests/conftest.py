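import numpy as np
import pytest

from asymmorph.io_landmarks import LandmarkConfiguration
from asymmorph.procrustes import standardize_mean
from asymmorph.synthetic import grid_config
from asymmorph.tps_warps import partial_warp_basis


@pytest.fixture(scope="session")
def grid7_ref():
    """Standardized 7x7 grid mean form."""
    return standardize_mean(grid_config(7, 7))


@pytest.fixture(scope="session")
def grid7_basis(grid7_ref):
    return partial_warp_basis(grid7_ref)


@pytest.fixture(scope="session")
def grid5_ref():
    return standardize_mean(grid_config(5, 5))


@pytest.fixture(scope="session")
def grid5_basis(grid5_ref):
    return partial_warp_basis(grid5_ref)


@pytest.fixture(scope="session")
def decagon_ref():
    """A generic (asymmetric) 10-landmark form: no bending-energy ties."""
    rng = np.random.default_rng(2024)
    coords = rng.normal(size=(10, 2))
    return standardize_mean(
        LandmarkConfiguration(coords, [f"L{i+1}" for i in range(10)], "decagon")
    )
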