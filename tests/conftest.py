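import pytest

from mecsd.kernel import TimeGrid
from mecsd.model import baseline_params
from mecsd.scenarios import run_baseline


@pytest.fixture(scope="session")
def reference_params():
    """The shipped calibrated reference parameter set."""
    return baseline_params()


@pytest.fixture(scope="session")
def baseline_traj(reference_params):
    return run_baseline(reference_params)


@pytest.fixture(scope="session")
def monthly_grid():
    return TimeGrid(0.0, 120.0, 1.0)
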