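import numpy as np
import pytest

from dmlc2d import MachineConfig, MLCGeometry


@pytest.fixture(scope="session")
def geometry():
    return MLCGeometry.millennium120()


@pytest.fixture(scope="session")
def machine():
    """Default machine: 600 MU/min, 25 mm/s leaves, 500 MU scaling."""
    return MachineConfig()


@pytest.fixture(scope="session")
def fast_machine():
    """Idealized machine with unconstrained leaf speed (tau -> 0)."""
    return MachineConfig(max_leaf_speed=float("inf"))


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
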