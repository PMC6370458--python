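"""Shared fixtures: small simulated session pools, reused across tests.

Simulation is the expensive step, so pools are module-scoped and kept
small; tests that need different regimes build their own data inline.
"""

import numpy as np
import pytest

from effconn import build_simple_network
from effconn.simulate import SimulationConfig, make_session


@pytest.fixture(scope="session")
def network5_pool():
    """Ten sessions of Network 5 (two feeders -> 2-cycle -> sink), fresh
    coefficient draw per session, observed (noisy) BOLD."""
    rng = np.random.default_rng(11)
    cfg = SimulationConfig()
    sessions = []
    for _ in range(10):
        net = build_simple_network(5, "amplifying", rng)
        sessions.append(make_session(cfg, net, rng))
    return sessions


@pytest.fixture(scope="session")
def network1_pool():
    """Ten sessions of Network 1 (five-node ring with one 2-cycle)."""
    rng = np.random.default_rng(7)
    cfg = SimulationConfig()
    sessions = []
    for _ in range(10):
        net = build_simple_network(1, "amplifying", rng)
        sessions.append(make_session(cfg, net, rng))
    return sessions


def make_skewed_pair(seed: int, n: int = 5000, coef: float = 0.5):
    """A centered linear non-Gaussian pair x -> y with exponential sources."""
    rng = np.random.default_rng(seed)
    x = rng.exponential(1.0, n)
    x -= x.mean()
    e = rng.exponential(1.0, n)
    e -= e.mean()
    y = coef * x + 0.5 * e
    y -= y.mean()
    return x, y
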