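import numpy as np
import pytest

from cros import build_network, simulate


@pytest.fixture(scope="session")
def small_net():
    """A small network at the oscillation-onset parameter point."""
    return build_network(L=20, ell=7, r_E=0.12, r_I=0.60, seed=7)


@pytest.fixture(scope="session")
def small_trace(small_net):
    return simulate(small_net, n_steps=2 ** 15, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
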