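import numpy as np
import pytest

from strfkit import build_bank


@pytest.fixture(scope="session")
def bank():
    """Default Gabor bank (63 real atoms at the 21 x 50 patch)."""
    return build_bank()


@pytest.fixture(scope="session")
def small_bank():
    """Sparse bank for fast matching-pursuit tests."""
    return build_bank(omega_t_grid=[0.0, 25.0, 125.0], omega_s_grid=[0.0, 0.25])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
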