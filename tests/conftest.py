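import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noesa.structures import TorsionSet, rebuild_from_torsions
from noesa.synthetic import packaged_fixture
from noesa.topology import default_topology

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture(scope="session")
def fixture(topo):
    """(spec, truth, restraints, perturbed start) of the packaged 24-mer."""
    return packaged_fixture(topo)


@pytest.fixture(scope="session")
def helix(topo):
    """Ideal polyalanine-like helix, 12 residues."""
    t = TorsionSet()
    for i in range(12):
        if i > 0:
            t[(i, "phi")] = -57.0
            t[(i, "omega")] = 180.0
        t[(i, "psi")] = -47.0
    return rebuild_from_torsions(t, topo, "A" * 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
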