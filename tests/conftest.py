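import numpy as np
import pytest

from dynpet.framing import DEFAULT_PROTOCOL, build_frame_schedule
from dynpet.input_function import feng_aif
from dynpet.kinetics import KineticParams


@pytest.fixture(scope="session")
def protocol_schedule():
    """The 28-frame, 65-min chest acquisition schedule."""
    return build_frame_schedule(DEFAULT_PROTOCOL)


@pytest.fixture(scope="session")
def aif():
    """Packaged tri-exponential arterial input on a 1-s grid over 65 min."""
    return feng_aif()


@pytest.fixture(scope="session")
def lesion_truth():
    """Reference lesion kinetics used across simulate-then-fit tests."""
    return KineticParams(0.12, 0.25, 0.06)


@pytest.fixture(scope="session")
def lesion_tac(lesion_truth, aif, protocol_schedule):
    from dynpet.kinetics import simulate_tissue_tac

    return simulate_tissue_tac(lesion_truth, aif, protocol_schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
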