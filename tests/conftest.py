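import numpy as np
import pytest

from neurofp import (BinaryPattern, NeuronParams, SimulationConfig,
                     make_single_protocol, make_topology, run_simulation)

SPONT = BinaryPattern((1, 1, 1, 1, 1), "spontaneous")
FP = BinaryPattern((1, 0, 1, 0, 1), "A")


@pytest.fixture(scope="session")
def spont():
    return SPONT


@pytest.fixture(scope="session")
def fingerprint():
    return FP


@pytest.fixture(scope="session")
def small_topology():
    """20x20 regular torus: big enough for collective dynamics, cheap."""
    return make_topology(20, 0.0)


def quick_run(p_e=0.05, p_r=0.8, side=20, p=0.0, steps=3000, seed=0,
              stim=None, t_on=500, duration=2000, **kw):
    """Small-network run helper shared across test modules."""
    topo = make_topology(side, p, seed=seed + 1)
    params = NeuronParams(p_e=p_e, p_r=p_r, spontaneous=SPONT)
    proto = None
    if stim is not None:
        proto = make_single_protocol(stim, (side * side // 2,), t_on, duration)
    cfg = SimulationConfig(topo, params, steps, seed, protocol=proto, **kw)
    return run_simulation(cfg)
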