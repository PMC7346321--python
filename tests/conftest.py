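import numpy as np
import pytest

from endcnn.synth import SynthConfig, generate_document


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture(scope="session")
def small_docs():
    """A handful of synthetic documents shared across tests."""
    gen = np.random.default_rng(7)
    cfg = SynthConfig(seed=7)
    return [generate_document(cfg, gen) for _ in range(30)]
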