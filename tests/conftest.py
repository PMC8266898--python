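import numpy as np
import pytest

from mildnet import SyntheticProfile, generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_samples_64():
    """Four clean 64x64 synthetic samples shared across tests."""
    profile = SyntheticProfile(regime="clean", image_size=(64, 64),
                               contrast=1.0, noise_sd=0.02, seed=7)
    return generate_samples(profile, 4)


@pytest.fixture(scope="session")
def tiny_samples_16():
    """Twelve 16x16 samples for fast training-loop tests."""
    profile = SyntheticProfile(regime="clean", image_size=(16, 16),
                               n_objects=(1, 1), contrast=0.9, noise_sd=0.02, seed=3)
    return generate_samples(profile, 12)
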