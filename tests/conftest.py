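import numpy as np
import pytest

from amynuc.constants import AB42
from amynuc.library_design import LibraryDesign, paper_designs


@pytest.fixture(scope="session")
def designs():
    return paper_designs()


@pytest.fixture()
def small_design():
    """A 3-position NNK double-mutant design over the C-terminus."""
    return LibraryDesign.from_scheme("mini", (40, 41, 42), "NNK", AB42, max_order=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
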