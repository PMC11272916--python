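import numpy as np
import pytest

from inkmol import chem_core
from inkmol.depiction import DepictionParams, render


@pytest.fixture(scope="session")
def vocab():
    return chem_core.Vocabulary()


@pytest.fixture(scope="session")
def corpus4():
    """Exhaustive C/H/O corpus up to 4 heavy atoms, at most one ring."""
    return chem_core.enumerate_cho(4, 1)


@pytest.fixture(scope="session")
def corpus5():
    """Exhaustive C/H/O corpus up to 5 heavy atoms, at most one ring."""
    return chem_core.enumerate_cho(5, 1)


@pytest.fixture(scope="session")
def ester_image():
    """A default-parameter rendering of a branched ester (the kind of
    structure volunteers were asked to draw)."""
    return render("CCC(C)COC(=O)C(C)CC", DepictionParams(), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
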