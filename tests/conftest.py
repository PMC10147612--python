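import pytest

from ferrispec import DEFERIPRONE, TransferrinParameters


@pytest.fixture(scope="session")
def tf_params() -> TransferrinParameters:
    return TransferrinParameters()


@pytest.fixture(scope="session")
def deferiprone():
    return DEFERIPRONE
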