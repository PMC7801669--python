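import numpy as np
import pytest

from muscleqmri.epg import build_t2_dictionary


@pytest.fixture(scope="session")
def small_dictionary():
    """A 20x5 (T2 x B1) dictionary, large enough for matcher oracle tests."""
    t2_grid = np.linspace(10.0, 60.0, 20)
    b1_grid = np.linspace(0.6, 1.1, 5)
    return build_t2_dictionary(t2_grid, b1_grid, esp_ms=5.15, n_echoes=32)


@pytest.fixture(scope="session")
def default_dictionary():
    """The full default dictionary (built once per session)."""
    return build_t2_dictionary()
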