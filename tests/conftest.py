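import pytest

from chdimpact import calibrated_baseline, calibrated_effect_parameters


@pytest.fixture(scope="session")
def baseline():
    """Calibrated synthetic demographic baseline (deterministic)."""
    return calibrated_baseline()


@pytest.fixture(scope="session")
def params(baseline):
    """Calibrated synthetic effect parameters."""
    return calibrated_effect_parameters(baseline)
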