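import numpy as np
import pytest

import dynome as dy


@pytest.fixture
def small_connectome():
    """10-neuron random network with both layers populated."""
    return dy.random_connectome(dy.SynthSpec(
        n=10, gap_density=0.25, syn_density=0.3, inhibitory_fraction=0.3,
        seed=42))


@pytest.fixture
def cfg():
    return dy.SolverConfig(seed=7)


def prepared_params(c, I_arb=0.0):
    """ModelParams for a connectome with the threshold vector solved."""
    p = dy.ModelParams.for_connectome(c)
    p.vth_mV = dy.compute_vth(c, p, I_arb)
    return p


@pytest.fixture
def params(small_connectome):
    return prepared_params(small_connectome)
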