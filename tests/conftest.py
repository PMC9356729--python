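import numpy as np
import pytest

from errophylo.simulate import simulate_coalescent, simulate_yule
from errophylo.substitution import (BinaryModelParams, Gt16ModelParams,
                                    build_binary_q, build_gt16_q)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def binary_q():
    return build_binary_q(BinaryModelParams(0.7))


@pytest.fixture
def gt16_q(rng):
    return build_gt16_q(Gt16ModelParams(rng.dirichlet(np.ones(6)),
                                        rng.dirichlet(np.full(16, 3.0))))


def random_gt16_q(rng, normalize=True):
    return build_gt16_q(Gt16ModelParams(rng.dirichlet(np.ones(6)),
                                        rng.dirichlet(np.full(16, 3.0))),
                        normalize=normalize)


@pytest.fixture
def yule_tree(rng):
    return simulate_yule(6, 5.0, rng)


@pytest.fixture
def coalescent_tree(rng):
    return simulate_coalescent(5, 0.5, rng)
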