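import numpy as np
import pytest

from degenexp.chromosomes import ChromosomeTable, fire_ant_table


@pytest.fixture(scope="session")
def ant_table() -> ChromosomeTable:
    return fire_ant_table()


@pytest.fixture
def small_table() -> ChromosomeTable:
    """Two small chromosomes; chr2 is social with a 70 kb supergene."""
    return ChromosomeTable(
        names=("chr1", "chr2"),
        lengths=(150_000, 100_000),
        social="chr2",
        supergene_interval=(20_000, 90_000),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
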