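import numpy as np
import pytest

from knockon.core import initial_superposition


@pytest.fixture
def rho0():
    return initial_superposition()


@pytest.fixture
def short_grid():
    """Coarse half-window grid for cheap integration tests."""
    return np.linspace(0.0, 2e-7, 401)
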