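import numpy as np
import pytest

import tatkit as tk


@pytest.fixture(scope="session")
def at211():
    return tk.AT211


@pytest.fixture(scope="session")
def table1(at211):
    """Packaged biodistribution fixture (15 organs x 5 time points)."""
    return tk.load_reference_biodistribution()


@pytest.fixture(scope="session")
def reference_doses():
    """Published absorbed-dose coefficients (Gy/MBq) for comparison."""
    return tk.load_reference_dose_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
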