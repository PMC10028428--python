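import math

import numpy as np
import pytest

from qbnet import (
    InitSpec,
    build_stg,
    find_attractors,
    fixture_cortical,
    generate_random_network,
    parse_rules,
)


@pytest.fixture(scope="session")
def cortical():
    return fixture_cortical()


@pytest.fixture(scope="session")
def cortical_stg(cortical):
    return build_stg(cortical)


@pytest.fixture(scope="session")
def cortical_attractors(cortical):
    return find_attractors(cortical)


@pytest.fixture
def ring_negation():
    """A <- !B, B <- !A: two fixed points (01, 10) and the 2-cycle {00, 11}."""
    return parse_rules("targets, factors\nA, !B\nB, !A\n")


@pytest.fixture
def identity_net2():
    return parse_rules("targets, factors\nA, A\nB, B\n")


def random_init_spec(net, rng, allow_frozen=True):
    thetas = tuple(float(t) for t in rng.uniform(0.0, math.pi, net.n))
    frozen = frozenset()
    if allow_frozen and net.n > 1:
        k = int(rng.integers(0, min(net.n - 1, 2) + 1))
        if k:
            frozen = frozenset(
                str(c) for c in rng.choice(net.components, size=k, replace=False)
            )
    return InitSpec(thetas, frozen)
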