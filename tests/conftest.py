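import numpy as np
import pytest

from synagg.cg_model import ForceFieldParams, build_system


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def small_system():
    """10 monomers, 30% doped, in a roomy periodic box."""
    return build_system(10, 0.3, 16.0, seed=7)


@pytest.fixture(scope="session")
def random_states():
    """Assorted random small systems for oracle-equivalence checks."""
    states = []
    rng = np.random.default_rng(123)
    for k in range(50):
        n = int(rng.integers(4, 12))
        box = float(rng.uniform(15.5, 24.0))
        states.append(build_system(n, float(rng.uniform(0, 1)), box, seed=int(rng.integers(1 << 30))))
    return states
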