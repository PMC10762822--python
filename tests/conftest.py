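import warnings

import numpy as np
import pytest

from carenet.pipeline import RunConfig, two_stage_analysis
from carenet.simulate import make_scenario

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message="possible separation.*")


@pytest.fixture(scope="session")
def small_signal_bundle():
    """One modest signal-scenario claims bundle shared across tests."""
    return make_scenario("signal", seed=314, n_patients=400)


@pytest.fixture(scope="session")
def small_analysis(small_signal_bundle):
    """Full two-stage analysis of the shared bundle."""
    b = small_signal_bundle
    cfg = RunConfig(input_dir=".", out_dir=".", seed=314)
    return two_stage_analysis(b.visits, b.diagnoses, b.patients,
                              b.timevarying, b.outcomes, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
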