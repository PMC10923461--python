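import numpy as np
import pytest

from ripplenet.params import DimensionlessParams, PhysicalParams


@pytest.fixture(scope="session")
def defaults():
    """Dimensionless defaults as printed (D = 0.04)."""
    return DimensionlessParams()


@pytest.fixture(scope="session")
def physical_defaults():
    return PhysicalParams()


@pytest.fixture(scope="session")
def small_net():
    return DimensionlessParams(N=200)


@pytest.fixture(scope="session")
def sparse_sim():
    """One cached sparse-synchrony run (N = 1000, I_ext = 0.55 nA)."""
    from ripplenet.network import simulate
    from ripplenet.params import drive_to_dimensionless
    ie = drive_to_dimensionless(0.55)
    return simulate(DimensionlessParams(N=1000), ie, duration=2050.0,
                    dt=0.01, seed=12)
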