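import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import infinet as inf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return inf.fixture_catalog()


@pytest.fixture(scope="session")
def synth_small():
    """A 300-node synthetic network with matrices, for mid-size checks."""
    net, panel = inf.generate_network(inf.SyntheticSpec(N=300, seed=5))
    return net, panel, inf.build_transition_matrices(net)


def random_network(rng: np.random.Generator, n: int, m: int) -> inf.DirectedNetwork:
    """A random directed network on n named nodes with ~m edges."""
    pairs = []
    for _ in range(m):
        u, v = rng.integers(n, size=2)
        pairs.append((f"x{u}", f"x{v}"))
    # register all nodes so N is exactly n
    return inf.DirectedNetwork.from_named_edges(
        pairs, extra_nodes=[f"x{i}" for i in range(n)]
    )
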