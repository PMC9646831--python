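import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from sacflow.geometry_mesh import (
    SacShape,
    build_idealized_aneurysm,
    generate_mesh,
)
from sacflow.rheology import BloodProperties


@pytest.fixture(scope="session")
def default_geometry():
    return build_idealized_aneurysm()


@pytest.fixture(scope="session")
def default_mesh(default_geometry):
    return generate_mesh(default_geometry, 5.0e-4)


@pytest.fixture(scope="session")
def straight_channel():
    return build_idealized_aneurysm(
        parent_width=4.0e-3,
        parent_length=40.0e-3,
        curvature=0.0,
        sac_shape=SacShape.NONE,
    )


@pytest.fixture(scope="session")
def channel_mesh(straight_channel):
    return generate_mesh(straight_channel, 4.0e-4)


@pytest.fixture(scope="session")
def newtonian_blood():
    return BloodProperties(model="newtonian", mu_inf_override=3.5e-3, density=1060.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
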