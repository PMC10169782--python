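import pytest
from hypothesis import settings

from dropgrow.quantify import QuantConfig
from dropgrow.synthetic import standard_fixture_set

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# absolute threshold: well above fluorescence read noise (sigma 150 over a
# background of 100), far below the spot amplitude
FIXTURE_THRESHOLD = 850.0


@pytest.fixture(scope="session")
def fixture_set():
    """The versioned synthetic benchmark: 3 images x 20 droplets, SNR 3/5/10."""
    return standard_fixture_set()


@pytest.fixture(scope="session")
def quant_config():
    return QuantConfig(radius_range=(28, 48), threshold=FIXTURE_THRESHOLD)
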