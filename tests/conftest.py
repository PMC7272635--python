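import numpy as np
import pytest

from spheropore.geometry import make_geometry, build_mesh
from spheropore.params import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def sphere_mesh_coarse():
    """45 um sphere in the standard 400 um box, coarse but usable."""
    return build_mesh(make_geometry(90e-6, 1.0, 400e-6), 8e-6)


@pytest.fixture(scope="session")
def prolate_mesh_coarse():
    """1:4 prolate cell (45 / 11.25 um semi-axes), coarse mesh."""
    return build_mesh(make_geometry(90e-6, 4.0, 400e-6), 8e-6)
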