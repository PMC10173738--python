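import numpy as np
import pytest

from mtpush.mt_dynamics import CatastropheModel, KineticParams
from mtpush.simulator import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def mal3_model():
    return CatastropheModel(step_parameter=3.6, timescale_parameter=35.0, tau0=25.0)


@pytest.fixture
def kinetics(mal3_model):
    return KineticParams(
        v_grow=0.05,
        v_contact=0.017,
        v_shrink=0.15,
        stall_force=5.0,
        flexural_rigidity=1.25,
        catastrophe=mal3_model,
    )


@pytest.fixture(scope="session")
def wt_trajectory():
    """One full WT-like run shared by read-only tests."""
    return simulate(SimConfig(seed=42))
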