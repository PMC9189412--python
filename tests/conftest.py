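import numpy as np
import pytest
from hypothesis import settings

from spikelet.synthgen import SyntheticSpikeParams, generate_spike

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_sample():
    """One noise-free synthetic spike with default geometry (19 spikelets)."""
    return generate_spike(SyntheticSpikeParams(seed=0))


@pytest.fixture(scope="session")
def noisy_sample():
    """Same scene with moderate pixel noise."""
    return generate_spike(SyntheticSpikeParams(seed=0, noise_sigma=5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
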