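"""Shared fixtures: branch tables are expensive, so build each once."""

import numpy as np
import pytest

from emp_popsim.bifurcation import scan_bifurcation
from emp_popsim.params import core_params, dnp63a_params, grhl2_params


@pytest.fixture(scope="session")
def core_table():
    return scan_bifurcation(core_params())


@pytest.fixture(scope="session")
def grhl2_table():
    return scan_bifurcation(grhl2_params())


@pytest.fixture(scope="session")
def dnp63a_table():
    return scan_bifurcation(dnp63a_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
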