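import numpy as np
import pytest

from vhhrisk import default_campaign_config, default_registry, generate_campaign


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def campaign(registry):
    """Default synthetic campaign at the package's default seed."""
    return generate_campaign(default_campaign_config(registry, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
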