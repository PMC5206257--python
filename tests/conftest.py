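import numpy as np
import pytest

from hybridsolv import builder
from hybridsolv.io import packaged_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 53-compound prediction table."""
    return packaged_table1()


@pytest.fixture(scope="session")
def small_water_box():
    """60 CG waters in a 13.4 A box (usable with a 6 A cutoff)."""
    return builder.build_box("water", 60, 13.4, seed=101)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(2024))
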