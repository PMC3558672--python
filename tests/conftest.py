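import numpy as np
import pytest

from ovisim import default_config


@pytest.fixture
def no_aging_config():
    """Default fly with senescence switched off (capped at 250 days)."""
    return default_config(
        seed=1, **{"energy.beta1": 0.0, "protein.beta2": 0.0, "max_days": 250}
    )


@pytest.fixture
def aging_config():
    """The curated default (m-regime) fly."""
    return default_config(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
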