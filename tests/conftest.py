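import numpy as np
import pytest

from chansuqc.compounds import load_compound_db
from chansuqc.quant import load_batch_contents, load_calibration_table


@pytest.fixture(scope="session")
def db():
    return load_compound_db()


@pytest.fixture(scope="session")
def contents_table():
    return load_batch_contents()


@pytest.fixture(scope="session")
def curves():
    return load_calibration_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
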