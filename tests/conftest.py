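import numpy as np
import pytest

import nonrev as nv


@pytest.fixture(scope="session")
def lg():
    return nv.load_builtin("LG")


@pytest.fixture(scope="session")
def jc20():
    """20-state Jukes-Cantor analogue: all exchangeabilities 1, uniform pi."""
    r = np.ones((20, 20))
    np.fill_diagonal(r, 0.0)
    return nv.build_reversible(r, np.full(20, 0.05), name="JC20")


@pytest.fixture(scope="session")
def nq_strong():
    """A strongly nonreversible random matrix (the 'strong signal' fixture)."""
    return nv.random_nonreversible_matrix(7, asymmetry=1.0)


@pytest.fixture(scope="session")
def tree6():
    return nv.random_rooted_tree(6, 17)
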