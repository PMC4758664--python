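import numpy as np
import pytest

from bepith import SimParams, run_simulation
from bepith.fixtures import FixtureSpec


@pytest.fixture(scope="session")
def small_sim():
    """One small but non-trivial tumor (2000 cells) at the fitted setting."""
    params = SimParams(lattice_side=120, max_cells=2000, max_steps=100_000)
    return run_simulation(params, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def mutation_fixture():
    spec = FixtureSpec(seed=3)
    from bepith.fixtures import gen_mutation_profile

    return gen_mutation_profile(spec)
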