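import numpy as np
import pytest

from methmf.reaction_model import Params
from methmf.simulator import SimConfig, gillespie_run


@pytest.fixture(scope="session")
def small_run():
    """A modest steady-state run reused by several read-only tests."""
    p = Params(a=0.2, x=1.0, y=1.0)
    return gillespie_run(p, SimConfig(N=30, T=400, seed=90210))


@pytest.fixture
def rng():
    return np.random.default_rng(12)
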