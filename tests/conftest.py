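import numpy as np
import pytest
from hypothesis import settings

from r2hat.grid import ConditionGrid, simulate_grid
from r2hat.params import EchoTimes
from r2hat.phantom import PhantomSpec, generate_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def te() -> EchoTimes:
    return EchoTimes()


@pytest.fixture(scope="session")
def grid() -> ConditionGrid:
    """Noise-free pool amplitudes over the full tissue-condition grid."""
    return simulate_grid()


@pytest.fixture(scope="session")
def grid_r2(grid, te) -> np.ndarray:
    """Per-alpha log-linear R2* over the grid (n_mwf, n_res, n_alpha)."""
    return grid.r2star(te)


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free single-session phantom."""
    return generate_phantom(PhantomSpec(seed=5, snr_te0=None))


@pytest.fixture(scope="session")
def phantom_noisy():
    """Noisy single-session phantom at the protocol SNR."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_hcm():
    """Noise-free phantom with hollow-cylinder frequency offsets enabled."""
    from r2hat.params import HCMParams

    return generate_phantom(PhantomSpec(seed=11, snr_te0=None, hcm=HCMParams()))
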