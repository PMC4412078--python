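import networkx as nx
import numpy as np
import pytest

import netentropy as ne


@pytest.fixture(scope="session")
def triangle():
    return ne.Network.from_networkx(nx.complete_graph(["a", "b", "c"]))


@pytest.fixture(scope="session")
def star4():
    """Star with one centre ('c') and 4 leaves."""
    return ne.Network.from_networkx(
        nx.star_graph(["c", "l1", "l2", "l3", "l4"])
    )


@pytest.fixture(scope="session")
def path3():
    return ne.Network.from_networkx(nx.path_graph(["a", "b", "c"]))


@pytest.fixture(scope="session")
def k5():
    return ne.Network.from_networkx(nx.complete_graph(5))


def random_instances(n, V=60, mean_degree=6, seed0=1000):
    """Alternating ER/BA networks with heterogeneous positive expression."""
    out = []
    for i in range(n):
        seed = seed0 + i
        if i % 2 == 0:
            net = ne.generate_er(V, mean_degree, seed)
        else:
            net = ne.generate_scale_free(V, mean_degree, seed)
        rng = np.random.default_rng(seed)
        expr = rng.uniform(0.5, 16.0, net.V)
        out.append((net, expr))
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """The shipped synthetic fixture: BA network, hub-up-regulated group B."""
    return ne.generate_cohort(ne.SyntheticCohortSpec(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Faster variant for unit tests that only need qualitative structure."""
    spec = ne.SyntheticCohortSpec(V=400, n_A=10, n_B=10, seed=7)
    return ne.generate_cohort(spec)
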