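import numpy as np
import pytest

from nethop import build_cell, mep_frame, radii_geometric, to_bead_network


@pytest.fixture(scope="session")
def cube():
    return build_cell(6)


@pytest.fixture(scope="session")
def tetra():
    return build_cell(4)


@pytest.fixture(scope="session")
def cube_radii(cube):
    return radii_geometric(cube)


@pytest.fixture(scope="session")
def tetra_radii(tetra):
    return radii_geometric(tetra)


@pytest.fixture(scope="session")
def tetra_network(tetra):
    return to_bead_network(tetra, N=4, replicate_neighbors=True)


@pytest.fixture(scope="session")
def tetra_frame(tetra):
    return mep_frame(tetra, 0)
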