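import numpy as np
import pytest

import transandes as ta
from transandes.dec import DECParams


@pytest.fixture(scope="session")
def hub_space():
    """Three areas, Amazon-only hub adjacency, max two-area ranges."""
    return ta.andes_amazon_space()


@pytest.fixture(scope="session")
def two_area_space():
    areas = [ta.Area("A", "Amazon"), ta.Area("B", "Andes")]
    return ta.build_state_space(areas, 2, [("A", "B")])


@pytest.fixture(scope="session")
def table5_records():
    return ta.load_transitions()


@pytest.fixture()
def three_tip_tree():
    return ta.parse_newick("((a:1,b:1):1,c:2);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20130909)


@pytest.fixture(scope="session")
def small_fit():
    """A fitted DEC model on a small simulated data set (shared across
    tests that only need some reconstruction to inspect)."""
    tree = ta.simulate_yule_tree(8, 0.3, seed=11)
    space = ta.andes_amazon_space()
    hist = ta.simulate_dec_history(tree, space, DECParams(0.08, 0.01), "A",
                                   seed=5, condition_on_survival=True)
    model = ta.DECModel(tree, hist.tip_ranges, space)
    return model.fit(seed=0)
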