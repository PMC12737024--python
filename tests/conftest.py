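import numpy as np
import pytest
from scipy.optimize import brentq

from aclthreshold import (
    ActivationState,
    AnthropometricProfile,
    LandingScenario,
    SurfaceState,
    TissueParameters,
    average_profile,
    net_abduction_torque,
)


@pytest.fixture(scope="session")
def profile() -> AnthropometricProfile:
    """Cohort-average geometry: reproduces every reference coefficient."""
    return average_profile()


@pytest.fixture(scope="session")
def tissue() -> TissueParameters:
    return TissueParameters()


@pytest.fixture(scope="session")
def root_find_critical_grf(profile, tissue):
    """Independent oracle: bracketed root-find of the net torque in Fy.

    Deliberately avoids the closed-form solver: it evaluates the torque
    balance through the scenario API and bisects on the force.
    """

    def _solve(angle, activation=None, surface=None, prof=None):
        prof = prof or profile
        activation = activation or ActivationState()
        surface = surface or SurfaceState()

        def residual(fy):
            scenario = LandingScenario(angle, fy, prof, activation, surface)
            return net_abduction_torque(scenario, tissue)

        lo, hi = 0.0, 1e12
        assert residual(lo) < 0 < residual(hi)
        return brentq(residual, lo, hi, xtol=1e-9, rtol=8.9e-16)

    return _solve


@pytest.fixture(scope="session")
def one_degree_grid():
    return np.arange(1.0, 91.0)
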