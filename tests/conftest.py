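import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from colontme.estimation import derive_parameters
from colontme.model import PARAM_NAMES, ParameterSet
from colontme.reference import CLUSTERS, steady_state


@pytest.fixture(scope="session")
def cluster_params():
    """Derived parameter set for each of the five reference clusters."""
    return {k: derive_parameters(steady_state(k)) for k in CLUSTERS}


def make_decoupled_params(A_TN: float = 2.0, delta_TN: float = 0.5,
                          **overrides) -> ParameterSet:
    """A parameter set with every coupling rate zero: each variable decays
    independently and naive T cells follow dTN/dt = A - delta*TN, the
    closed-form scalar oracle used across the sensitivity tests."""
    values = {name: 0.0 for name in PARAM_NAMES}
    values.update(
        A_TN=A_TN, delta_TN=delta_TN,
        delta_H=1.0, delta_mu1=1.0, delta_mu2=1.0, delta_Ig=1.0,
        delta_Gb=1.0, delta_Th=1.0, delta_TC=1.0, delta_Tr=1.0,
        delta_D=1.0, delta_M=1.0, delta_C=1.0, delta_N=1.0,
        C0=1.0, M0=1.0, alpha_NC=0.5,
    )
    values.update(overrides)
    return ParameterSet(values)


@pytest.fixture
def decoupled_params():
    return make_decoupled_params()


def decoupled_equilibrium(params: ParameterSet) -> np.ndarray:
    """Equilibrium of the decoupled system: TN = A/delta, all else zero."""
    x = np.zeros(len(PARAM_NAMES) * 0 + 14)
    x[0] = params["A_TN"] / params["delta_TN"]
    return x
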