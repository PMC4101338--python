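import numpy as np
import pytest

from xenoarray.simulate import SimulationConfig, simulate_dual_species

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dual-species dataset at default biology."""
    cfg = SimulationConfig(n_genes=40, transcript_length=300, seed=7)
    return simulate_dual_species(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
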