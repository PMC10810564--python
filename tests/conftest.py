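import numpy as np
import pytest

from brainco2.io import InputTrace
from brainco2.parameters import default_parameters
from brainco2.synthetic import ChallengeSpec, make_inputs


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def baseline_inputs(params):
    return (params.P_an, params.SaO2_n, params.PaCO2_n)


@pytest.fixture(scope="session")
def challenge_spec():
    return ChallengeSpec(seed=0)


@pytest.fixture(scope="session")
def challenge_inputs(challenge_spec):
    """Standard 600 s challenge, clean drivers."""
    return make_inputs(challenge_spec)


@pytest.fixture(scope="session")
def plateau_mask(challenge_spec, challenge_inputs):
    return challenge_spec.plateau_mask(challenge_inputs.t)


def constant_inputs(params, duration=600.0, dPaCO2=0.0, dMABP=0.0):
    """Constant-driver trace at (possibly shifted) baseline."""
    t = np.arange(0.0, duration, 1.0)
    return InputTrace(
        t=t,
        MABP=np.full_like(t, params.P_an + dMABP),
        SpO2=np.full_like(t, params.SaO2_n),
        PaCO2=np.full_like(t, params.PaCO2_n + dPaCO2),
    )


@pytest.fixture(scope="session")
def make_constant_inputs():
    return constant_inputs
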