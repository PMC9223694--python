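import numpy as np
import pytest

from hsr.model import (
    CellParameters,
    ModelParameters,
    TemperatureProtocol,
    steady_state,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def ref_cell(params):
    return CellParameters(hsf1_tot=params.hsf1_tot_ref, hsp0=1.0)


@pytest.fixture(scope="session")
def normothermic_state(params, ref_cell):
    """Fixed point of the reference cell at 37 degC (computed once)."""
    return steady_state(ref_cell, params)


@pytest.fixture(scope="session")
def protocol_43():
    """Standard experiment: 3 h at 43 degC inside a 37 degC window."""
    return TemperatureProtocol.step(43.0, 3.0, pre=1.0 / 6.0, post=1.0)


@pytest.fixture(scope="session")
def sampling_grid():
    """10-minute grid from -10 min to 4 h."""
    return np.arange(-1, 25) / 6.0
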