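import numpy as np
import pytest

from bathyrad import parse_newick
from bathyrad.simulate import (
    constant_rate_config,
    simulate_branching_times,
    tree_from_branching_times,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_bt():
    from bathyrad import BranchingTimes

    return BranchingTimes.from_ages([10.0, 6.0, 3.0])


@pytest.fixture
def yule_tree(rng):
    """A 30-tip Yule chronogram, crown age 40 Myr."""
    bt = simulate_branching_times(constant_rate_config(40.0, 0.08, n_tips=30), rng)
    return tree_from_branching_times(bt, rng)
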