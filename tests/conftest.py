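import numpy as np
import pytest

from platt.filterbank import design_filterbank


@pytest.fixture(scope="session")
def spec48():
    """The default 48 kHz filterbank design, shared across tests."""
    return design_filterbank(48000.0)


@pytest.fixture(scope="session")
def spec32():
    """A 32 kHz design (lowest admissible standard rate)."""
    return design_filterbank(32000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231101)
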