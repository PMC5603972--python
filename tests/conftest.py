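import numpy as np
import pytest

from talarmorph import synthetic
from talarmorph.dataio import PhyloTree


@pytest.fixture(scope="session")
def balanced8() -> PhyloTree:
    """Fixed 8-tip balanced ultrametric tree of height 3."""
    nwk = ("(((A:1,B:1):1,(C:1,D:1):1):1,"
           "((E:1,F:1):1,(G:1,H:1):1):1);")
    return PhyloTree.from_newick(nwk)


@pytest.fixture(scope="session")
def yule16() -> PhyloTree:
    return synthetic.sim_tree(16, 1.0, seed=101)


@pytest.fixture(scope="session")
def yule32() -> PhyloTree:
    return synthetic.sim_tree(32, 1.0, seed=202)


@pytest.fixture(scope="session")
def yule64() -> PhyloTree:
    return synthetic.sim_tree(64, 1.0, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
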