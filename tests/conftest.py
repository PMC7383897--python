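import numpy as np
import pytest

from spiralsort import donor_presets, default_focusing_model


@pytest.fixture(scope="session")
def presets():
    return donor_presets()


@pytest.fixture(scope="session")
def model():
    return default_focusing_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(np.random.SeedSequence(20240901))
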