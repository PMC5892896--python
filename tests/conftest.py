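import numpy as np
import pytest

from mtcsim import PopulationConfig, sample_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_population():
    """A 500-voter electorate at the default parameters."""
    return sample_population(PopulationConfig(n_voters=500, seed=42))
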