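import numpy as np
import pytest

from clockshift import (
    Alignment,
    HKYParams,
    SimulationSpec,
    fixture_primate_tree,
    parse_newick,
    simulate_alignment,
)


@pytest.fixture(scope="session")
def primate_tree():
    return fixture_primate_tree()


@pytest.fixture(scope="session")
def small_tree():
    """6-taxon rooted ultrametric tree with a focal class-1 stem branch."""
    nwk = (
        "((A:0.05,B:0.05):0.15,(((C:0.04,D:0.04):0.06#1,E:0.1):0.05,"
        "F:0.15):0.05);"
    )
    return parse_newick(nwk)


@pytest.fixture(scope="session")
def quartet_tree():
    return parse_newick("((A:0.1,B:0.25):0.12,(C:0.3,D:0.05):0.2);")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_alignment(small_tree):
    spec = SimulationSpec(
        tree=small_tree,
        model=HKYParams(kappa=3.0, gamma_shape=None),
        n_sites=2000,
        seed=7,
        class_rates={1: 1.5},
    )
    return simulate_alignment(spec)
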