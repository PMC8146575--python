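import numpy as np
import pytest

from kmfinite.simulate import JumpDiffusionSpec, simulate


@pytest.fixture(scope="session")
def ou_series():
    """Moderate-length Ornstein-Uhlenbeck trajectory (a=1, b=0.5)."""
    spec = JumpDiffusionSpec(a=1.0, b=0.5, lam=0.0, s=0.0, dt=0.01, seed=1234)
    return simulate(spec, 400_000)


@pytest.fixture(scope="session")
def jump_series():
    """Moderate-length jump-diffusion trajectory."""
    spec = JumpDiffusionSpec(a=0.5, b=0.5, lam=0.6, s=0.75, dt=0.01, seed=4321)
    return simulate(spec, 400_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
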