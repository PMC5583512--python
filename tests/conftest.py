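import numpy as np
import pytest

from armalign import presets, simulate
from armalign.genome import GenomeSpec


@pytest.fixture(scope="session")
def genome():
    return presets.caulobacter()


@pytest.fixture(scope="session")
def frag(genome):
    return simulate.synthetic_fragment_map(genome, seed=1)


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec(name="mini", length_bp=2000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
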