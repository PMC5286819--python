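import numpy as np
import pytest

from psomcs import (
    DesignSpec,
    Objective,
    RandomNetworkSpec,
    build_intervention,
    generate_random_network,
    loads_tabular,
)
from psomcs.synth import random_design, toy_design, toy_network

# simple linear chain: uptake -> A -> P secretion
CHAIN = """\
UP   irr  A:1
CONV irr  A:-1,P:1
SEC  irr  P:-1
"""

# diamond: two parallel internal routes from A to P
DIAMOND = """\
UP   irr  A:1
TOP  irr  A:-1,P:1
BOT  irr  A:-1,P:1
SEC  irr  P:-1
"""


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def toy_spec():
    return toy_design()


@pytest.fixture
def toy_problem_x1(toy_net, toy_spec):
    return build_intervention(toy_spec, [1.0], toy_net)


@pytest.fixture
def chain_net():
    return loads_tabular(CHAIN)


@pytest.fixture
def diamond_net():
    return loads_tabular(DIAMOND)


@pytest.fixture
def chain_spec():
    return DesignSpec(
        objectives=[Objective(name="p", numerator="SEC", role="product_min_yield")],
        reference=["UP"],
    )


def make_random_net(seed, m=5, n=10, n_exchange=4, branching=0.5, rev=0.2):
    return generate_random_network(
        RandomNetworkSpec(
            m=m, n=n, n_exchange=n_exchange, branching=branching,
            fraction_reversible=rev, seed=seed,
        )
    )


@pytest.fixture
def random_net_factory():
    return make_random_net


@pytest.fixture
def random_design_factory():
    return random_design
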