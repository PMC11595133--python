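import numpy as np
import pytest

from cernakit.pipeline import analyze
from cernakit.syndata import SimConfig, simulate


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


SMALL_CONFIG = SimConfig(
    n_mrna=60,
    n_lncrna=25,
    n_mirna=15,
    n_triplets=5,
    n_trans_pairs=2,
    planted_de_fraction=0.25,
    seed=123,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across read-only tests."""
    return simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    return analyze(small_sim)
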