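import numpy as np
import pytest

from recombmap.mapio import GeneticMap


@pytest.fixture
def uniform_map():
    """20 Mb chromosome at 1 cM/Mb."""
    return GeneticMap.from_rates("1", [0, 20_000_000], [1.0])


@pytest.fixture
def three_interval_map():
    """Hand-built map with three distinct rates."""
    return GeneticMap.from_rates("1", [0, 100_000, 250_000, 400_000], [0.5, 2.0, 1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
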