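import numpy as np
import pytest

from osteoadapt import ModelParameters, make_waveform
from osteoadapt.fixtures import (FixtureSpec, TRAPEZOID_TIMINGS,
                                 make_cells_and_network, make_section)

#: published calibration constants used as synthetic ground truth throughout
CAL = {
    "p_d_beta": 1.06859e-4,
    "q": 0.404736,
    "r_s": 0.436235,
    "eps_thres_ue": 856.126,
    "beta": 0.465,
    "h_nm_per_ue": 0.123,
    "d": 3.0,
}


@pytest.fixture(scope="session")
def cal():
    return dict(CAL)


@pytest.fixture(scope="session")
def trapezoid_rest():
    return make_waveform("trapezoid", TRAPEZOID_TIMINGS, rest_s=10.0)


@pytest.fixture(scope="session")
def trapezoid_norest():
    return make_waveform("trapezoid", TRAPEZOID_TIMINGS, rest_s=0.0)


@pytest.fixture(scope="session")
def lump_params():
    """Fitted-lump parameterization (valid at the calibration d = 3)."""
    return ModelParameters(q=CAL["q"], eps_thres_ue=CAL["eps_thres_ue"],
                           r_s=CAL["r_s"], p_d_beta=CAL["p_d_beta"],
                           h_nm_per_ue=CAL["h_nm_per_ue"])


@pytest.fixture(scope="session")
def split_params():
    """Explicit (p, beta) parameterization via the derived beta."""
    return ModelParameters(q=CAL["q"], eps_thres_ue=CAL["eps_thres_ue"],
                           r_s=CAL["r_s"], p=CAL["p_d_beta"] / CAL["d"] ** CAL["beta"],
                           beta=CAL["beta"], h_nm_per_ue=CAL["h_nm_per_ue"])


@pytest.fixture(scope="session")
def default_fixture():
    spec = FixtureSpec(seed=7)
    section = make_section(spec)
    network = make_cells_and_network(section, spec)
    return spec, section, network


@pytest.fixture(scope="session")
def small_fixture():
    spec = FixtureSpec(seed=3, n_osteocytes=60, n_osteoblasts_periosteal=16,
                       n_osteoblasts_endocortical=8, n_vertices=64)
    section = make_section(spec)
    network = make_cells_and_network(section, spec)
    return spec, section, network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
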