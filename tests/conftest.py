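import numpy as np
import pytest

from motorforge.synthetic_data import (
    MotorTrapParams,
    TrapTrace,
    make_reference_structure,
    simulate_trap_trace,
)


@pytest.fixture(scope="session")
def reference_structure():
    return make_reference_structure()


@pytest.fixture(scope="session")
def unbound_trace():
    """20 s of a permanently unbound bead at the default stiffness."""
    params = MotorTrapParams(initially_bound=False, reattach_rate=0.0,
                             duration=20.0, seed=11)
    return simulate_trap_trace(params)


def constant_trace(value: float, n: int = 1000, rate: float = 250.0,
                   k: float = 0.06) -> TrapTrace:
    return TrapTrace(times=np.arange(n) / rate,
                     force=np.full(n, float(value)),
                     spring_constant=k, sample_rate=rate, label="const")
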