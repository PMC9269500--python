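import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scintidose import materials, stopping, transport

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def abls_comp():
    return materials.abls()


@pytest.fixture(scope="session")
def water_comp():
    return materials.water()


@pytest.fixture(scope="session")
def abls_table(abls_comp):
    return stopping.build_table(abls_comp)


@pytest.fixture(scope="session")
def mc6_grid(abls_comp, abls_table):
    """A 6 MeV electron-beam dose grid shared by transport/range/image tests."""
    beam = transport.BeamSpec("electron", 6.0, 6.0, 30_000, seed=11)
    geom = transport.GeometrySpec(material=abls_comp)
    return transport.simulate_electron_beam(beam, geom, table=abls_table)


@pytest.fixture(scope="session")
def mc6_pdd(mc6_grid):
    return transport.pdd_from_dose_grid(mc6_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
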