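import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnprobe.processing import ProcessingConfig
from cnprobe.simulate import FrequencyFixture, InstrumentModel

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return InstrumentModel().grid()


@pytest.fixture(scope="session")
def fixture_table():
    return FrequencyFixture.load_default()


@pytest.fixture(scope="session")
def fit_config():
    """Reconstruction + baseline correction, no smoothing (used before fits)."""
    return ProcessingConfig(sg_window=None, fourier_cutoff=None)
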