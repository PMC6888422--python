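import warnings

import pytest

from sawrky import io_formats as io


@pytest.fixture(scope="session")
def family_rows():
    return io.load_family_fixture()


@pytest.fixture(scope="session")
def regulation():
    return io.load_regulation_fixture()


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
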