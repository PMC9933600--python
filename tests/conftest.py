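import numpy as np
import pytest

from nanoqspr import fit_pls, load_fixture_table1, validate_model


@pytest.fixture(scope="session")
def table1():
    return load_fixture_table1()


@pytest.fixture(scope="session")
def model2lv(table1):
    """The 2-LV, 5-descriptor model on the packaged dataset's 14 training rows."""
    return fit_pls(table1, 2)


@pytest.fixture(scope="session")
def fixture_validation(table1):
    """Full validation battery on the packaged dataset (model, report)."""
    return validate_model(table1, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
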