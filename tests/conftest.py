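import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fdss_abc.demography import SimulationConfig, builtin_model, toy_constant_size_model


@pytest.fixture(scope="session")
def sd_model():
    return builtin_model("SD")


@pytest.fixture(scope="session")
def md_model():
    return builtin_model("MD")


@pytest.fixture(scope="session")
def toy_model():
    return toy_constant_size_model()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()
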