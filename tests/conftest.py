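import pytest

from ceassay import default_inputs


@pytest.fixture(scope="session")
def base():
    """Published base case, Japanese recurrence-risk estimates."""
    return default_inputs("japan")


@pytest.fixture(scope="session")
def usuk(base):
    """Alternative scenario: US/UK validation-study recurrence risks."""
    return base.with_risk_source("us_uk")
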