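import numpy as np
import pytest

from helixfuse.fixtures import make_bundle, make_mock_receptor, make_screen_dataset


@pytest.fixture(scope="session")
def bundle():
    """Default six-helix bundle, 123 residues."""
    return make_bundle(seed=1)


@pytest.fixture(scope="session")
def receptor(bundle):
    """Mock receptor planted on the bundle's own windows (exact positive)."""
    return make_mock_receptor(bundle, seed=2)


@pytest.fixture(scope="session")
def screen_dataset():
    """Small end-to-end dataset: 8 models, half fusible."""
    return make_screen_dataset(n_models=8, fraction_fusible=0.5, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
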