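import numpy as np
import pytest

import reachconf as rc

# Scaled-down settings shared by tests that run full maximum-likelihood fits;
# accuracy/runtime trade-off is validated against the spec-default
# configuration in test_fitting.py.
FAST_INTEGRATION = rc.IntegrationConfig(radial_nodes=64, policy_table_step=2.0)
FAST_FIT = rc.FitConfig(n_starts=2, xtol=5e-3, tol=1e-2)


@pytest.fixture(scope="session")
def params_equal():
    """Observer with equal motor and proprioceptive noise (both 20 mm)."""
    return rc.ObserverParams(20.0, 20.0, 5.0)


@pytest.fixture(scope="session")
def control_300(params_equal):
    return rc.simulate_control_task(params_equal, 300, seed=101)


@pytest.fixture(scope="session")
def ideal_main_300(params_equal):
    return rc.simulate_main_task(rc.ModelKind.IDEAL, params_equal, 300,
                                 seed=102)


@pytest.fixture(scope="session")
def prospective_main_300(params_equal):
    return rc.simulate_main_task(rc.ModelKind.PROSPECTIVE, params_equal, 300,
                                 seed=103)
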