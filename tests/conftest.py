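import numpy as np
import pytest

import alphatune as at


@pytest.fixture(scope="session")
def basis():
    return at.make_basis(8)


@pytest.fixture(scope="session")
def design16():
    """Balanced 16-location design, 12 trials per location."""
    return at.make_design(12, 16, seed=11)


@pytest.fixture(scope="session")
def truth32():
    """Noiseless ground truth with 32 sensors and 8 latent channels."""
    mixing = at.make_mixing(32, 8, np.random.default_rng(5))
    return at.GroundTruth(mixing=mixing, tuning_depth=0.5, noise_sd=0.0)
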