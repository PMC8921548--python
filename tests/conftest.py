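import pytest

import cardiotriage


@pytest.fixture(scope="session")
def thresholds():
    return cardiotriage.Thresholds()


@pytest.fixture(scope="session")
def reference_cohort():
    """The deterministic 2,002-patient reference cohort and constraint table."""
    return cardiotriage.reference_cohort()
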