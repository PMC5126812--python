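import numpy as np
import pytest

from boneqol.eq5d import DIMENSIONS, LEVELS, ValueSet
from boneqol.io import load_england_value_set, load_table2_counts


@pytest.fixture(scope="session")
def england_vs() -> ValueSet:
    return load_england_value_set()


@pytest.fixture(scope="session")
def toy_vs() -> ValueSet:
    """Linear toy value set: each step up a level costs 0.05, so state
    21111 scores 0.95 and the floor is exactly 0."""
    dec = {(dim, lvl): 0.05 * (lvl - 1) for dim in DIMENSIONS for lvl in LEVELS}
    return ValueSet("toy-linear", dec)


@pytest.fixture(scope="session")
def table2_counts():
    return load_table2_counts()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2016)
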