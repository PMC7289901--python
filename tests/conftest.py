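import random

import pytest

from phylograft import SimulationParams, read_newick, simulate_bd_tree


@pytest.fixture
def basic_tree():
    """Three-tip ultrametric tree of height 2 used across examples."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_tree():
    return read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


def random_bd_tree(seed, n_tips=20, **kw):
    params = SimulationParams(
        n_tips=n_tips, birth_rate=1.0, death_rate=0.4, seed=seed, **kw
    )
    return simulate_bd_tree(params)


@pytest.fixture
def rng():
    return random.Random(20260920)
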