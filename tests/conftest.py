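import numpy as np
import pytest

from airsusc import GeneratorConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared across tests (read-only)."""
    cfg = GeneratorConfig(n_regions=12, n_respondents_per_region=1500, seed=7)
    return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
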