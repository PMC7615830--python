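import numpy as np
import pytest

from prospect import bear_fixture, init_network
from prospect.pcn import NetworkState, compute_errors


@pytest.fixture
def bear():
    return bear_fixture()


@pytest.fixture
def small_net():
    """4-layer sigmoid net, small enough for finite-difference oracles."""
    return init_network([3, 5, 4, 2], activation="sigmoid", seed=42)


def random_state(net, seed=0, batch=1):
    """A NetworkState with random activities (errors computed)."""
    rng = np.random.default_rng(seed)
    acts = [rng.normal(size=(n, batch)) for n in net.layer_sizes]
    return compute_errors(net, NetworkState(acts))


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g
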