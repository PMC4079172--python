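import pytest

from qcakit import load_fixture
from qcakit.fixtures import MODEL1_CONDITIONS, MODEL3_CONDITIONS


@pytest.fixture(scope="session")
def breastfeeding():
    """The bundled 12-study breastfeeding worked-example table."""
    return load_fixture()


@pytest.fixture(scope="session")
def model1():
    return MODEL1_CONDITIONS


@pytest.fixture(scope="session")
def model3():
    return MODEL3_CONDITIONS
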