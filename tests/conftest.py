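import logging

import numpy as np
import pytest

from coremf.simulate import SyntheticConfig, generate


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    logging.getLogger("coremf").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 0)."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
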