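import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cell_params():
    from cardiomef.ionic import CellParams
    return CellParams.for_cell_type("epi")


@pytest.fixture(scope="session")
def paced(cell_params):
    """Single cell paced to steady state at the 600 ms cycle length."""
    from cardiomef import protocols as pr
    return pr.paced_cell_state(cell_params, 600.0)


@pytest.fixture(scope="session")
def sac10(cell_params, paced):
    """SAC parameters calibrated at the baseline 10% trigger level."""
    from cardiomef.sac import calibrate_sac
    return calibrate_sac(0.10, cell_params, paced_state=paced.state)


@pytest.fixture(scope="session")
def baseline_run():
    """Baseline closed-loop run to steady state with default configuration."""
    from cardiomef import protocols as pr
    return pr.run_to_steady_state()


@pytest.fixture(scope="session")
def calcium_transient():
    """One cycle of the synthetic calcium transient at 1 ms sampling."""
    from cardiomef.drivers import CalciumTransientSpec, make_calcium
    return make_calcium(CalciumTransientSpec(), 1.0)


@pytest.fixture()
def mini_heart_cfg():
    from cardiomef.drivers import make_fixture
    return make_fixture("mini-heart")
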