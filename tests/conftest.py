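import numpy as np
import pytest
from hypothesis import settings

from pulsedamp import PhantomSpec, simulate_pc_series

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

GRID = (32, 32)
CENTER = (15, 15)


@pytest.fixture
def static_roi():
    roi = np.zeros(GRID, dtype=bool)
    roi[:6, :6] = True
    return roi


@pytest.fixture
def noiseless_phantom():
    """Noiseless LSA-like phantom, no wrap, vessel centred on a pixel."""
    spec = PhantomSpec(snr=np.inf, seed=0)
    series, truth = simulate_pc_series(spec)
    return spec, series, truth
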