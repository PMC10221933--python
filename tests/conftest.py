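import numpy as np
import pytest

from virusscout.io_formats import SmallRead
from virusscout.synthetic_data import SimGenomeParams, simulate_genome


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_reads(pairs) -> list[SmallRead]:
    return [SmallRead(read_id, seq) for read_id, seq in pairs]


@pytest.fixture(scope="session")
def genome():
    """A 6.5 kb simulated viral genome shared across tests."""
    return simulate_genome(SimGenomeParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
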