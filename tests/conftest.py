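import numpy as np
import pytest

from wmltm.response_model import ParticipantParams
from wmltm.task_design import generate_ltm_design, generate_wm_design


@pytest.fixture(scope="session")
def wm_design():
    return generate_wm_design(1)


@pytest.fixture(scope="session")
def ltm_design(wm_design):
    return generate_ltm_design(wm_design, 1)


@pytest.fixture()
def params():
    return ParticipantParams(
        k_true=1.6, g_old=0.4, beta_same=0.7, b_wm=0.6, d_novel=0.8,
        tau_ltm=0.5, b_ltm=0.5, g_old_ltm=0.3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
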