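import numpy as np
import pytest

from corouq.cohort import LVConfig, TreeConfig, generate_lv, generate_tree
from corouq.targets import OutletSet


@pytest.fixture(scope="session")
def small_tree():
    """6-outlet tree: fast enough for transient simulations in tests."""
    return generate_tree(6, seed=42)


@pytest.fixture(scope="session")
def tree14():
    return generate_tree(14, seed=1)


@pytest.fixture(scope="session")
def lv_small():
    return generate_lv(800, seed=2, config=LVConfig(total_flow=240.0))


@pytest.fixture(scope="session")
def outlets14(tree14):
    return OutletSet.from_tree(tree14)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
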