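import numpy as np
import pytest

import pangls as pg


@pytest.fixture(scope="session")
def three_tip():
    """The worked 3-tip tree ((A:1,B:1):1,C:2) with its known covariance."""
    phy = pg.read_newick("((A:1,B:1):1,C:2);")
    V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
    return phy, V


@pytest.fixture(scope="session")
def star_tree():
    return pg.read_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture(scope="session")
def yule48():
    """A fixed 48-tip ultrametric tree shared by the larger simulations."""
    phy = pg.simulate_yule_tree(48, birth_rate=1.0, seed=20240901)
    _, V = pg.phylo_covariance(phy)
    return phy, V


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
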