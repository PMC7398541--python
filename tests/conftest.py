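import numpy as np
import pytest

from cisrd.fiber import FiberModel, FiberParams
from cisrd.geometry import ArrayLayout


@pytest.fixture(scope="session")
def fiber_model():
    """One shared default fiber (compiles the numba kernel once)."""
    return FiberModel(FiberParams())


@pytest.fixture(scope="session")
def near_layout():
    return ArrayLayout(electrode_anf_distance_mm=0.23)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
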