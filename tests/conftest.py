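import numpy as np
import pytest

from nervesim.fibers import MyelinatedFiber, UnmyelinatedFiber
from nervesim.solver import Clamp, SimConfig, simulate_fiber
from nervesim.stimulus import make_pulse


@pytest.fixture(scope="session")
def myelinated_ap_result():
    """A propagating action potential on a 10 µm myelinated fiber,
    shared across tests that only read the traces."""
    fiber = MyelinatedFiber(10.0, n_nodes=21)
    clamp = Clamp("current", 0, make_pulse(0.1, 0.01, 0.1))
    config = SimConfig(dt=0.002, t_sim=1.5, record_Imem=True)
    result = simulate_fiber(fiber, clamps=[clamp], config=config)
    return fiber, result


@pytest.fixture(scope="session")
def unmyelinated_ap_result():
    fiber = UnmyelinatedFiber(1.0, length=4000.0, n_compartments=160)
    clamp = Clamp("current", 0, make_pulse(0.1, 0.02, 0.5))
    config = SimConfig(dt=0.005, t_sim=14.0, record_Imem=True)
    result = simulate_fiber(fiber, clamps=[clamp], config=config)
    return fiber, result
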