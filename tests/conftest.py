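import numpy as np
import pytest

from mmvital import RadarConfig, design_lens


@pytest.fixture(scope="session")
def default_layout():
    """Quantized 37-element lens layout, shared across read-only tests."""
    return design_lens()


@pytest.fixture(scope="session")
def radar_config():
    return RadarConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
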