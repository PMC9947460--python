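import numpy as np
import pytest

from sansfem.anatomy import AnatomyParams, build_anatomy
from sansfem.mesh import mesh_geometry


@pytest.fixture(scope="session")
def baseline_geom():
    return build_anatomy(AnatomyParams())


@pytest.fixture(scope="session")
def coarse_mesh(baseline_geom):
    return mesh_geometry(baseline_geom, "coarse", 2)


@pytest.fixture()
def rng():
    # fresh stream per test so outcomes do not depend on execution order
    return np.random.default_rng(20230209)
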