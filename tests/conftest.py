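import pytest

from electrocyte import epm_default, resting_state


@pytest.fixture(scope="session")
def params():
    return epm_default()


@pytest.fixture(scope="session")
def rest(params):
    return resting_state(params)
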