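import numpy as np
import pytest

from runtumble.chemotaxis import EcoliParams
from runtumble.stimuli import SignalTrace
import runtumble.stimuli as stimuli_mod


@pytest.fixture(scope="session")
def params_ii() -> EcoliParams:
    return EcoliParams(model_id="II")


@pytest.fixture(scope="session")
def params_iii() -> EcoliParams:
    return EcoliParams(model_id="III")


def step_trace(t_max=400.0, t_jump=50.0, lo=0.0, hi=2.0, dt=0.1) -> SignalTrace:
    """A single-step PWC trace (lo -> hi at t_jump) with analytic derivatives."""
    func = stimuli_mod._PWC(np.array([0.0, t_jump, t_max]), np.array([lo, hi]))
    t = np.arange(0.0, t_max + dt / 2, dt)
    return SignalTrace(
        t=t, s=func.value(t), s_prime=func.d1(t), s_doubleprime=func.d2(t),
        jump_times=func.jump_times, kink_times=func.kink_times, func=func,
    )


@pytest.fixture(scope="session")
def step() -> SignalTrace:
    return step_trace()
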