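import numpy as np
import pandas as pd
import pytest

from metacons import phylo, synthetic


@pytest.fixture(scope="session")
def cherry_tree():
    return phylo.parse_phylogeny("(A:1,B:1);")


@pytest.fixture(scope="session")
def star4_tree():
    return phylo.parse_phylogeny("(A:1,B:1,C:1,D:1);")


@pytest.fixture(scope="session")
def tree16():
    return synthetic.simulate_tree(16, seed=101)


@pytest.fixture(scope="session")
def tree64():
    return synthetic.simulate_tree(64, seed=202)


@pytest.fixture(scope="session")
def toy_model():
    return synthetic.toy_kinetic_model()


@pytest.fixture(scope="session")
def toy_wildtype(toy_model):
    from metacons.kinetics import steady_state

    ss = steady_state(toy_model)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def multiorgan_dataset():
    """26-species, 4-organ synthetic dataset with known per-organ rates."""
    tree = synthetic.simulate_tree(26, seed=7)
    tm, truth = synthetic.simulate_multiorgan_traits(tree, n_metabolites=30, seed=8)
    table = phylo.mcs_table(tree, tm)
    return tree, tm, truth, table
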