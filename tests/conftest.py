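import numpy as np
import pytest

from porinflux.calibration import HillFit
from porinflux.constants import HILL_COEF, HILL_K_HALF_UM, HILL_VMAX_AU


@pytest.fixture
def reference_hill() -> HillFit:
    """The reference free-enzyme calibration (v_max, K_0.5, h)."""
    return HillFit(v_max=HILL_VMAX_AU, k_half=HILL_K_HALF_UM, h=HILL_COEF, r2=1.0)


@pytest.fixture
def flash_truth():
    """A well-conditioned flash decay: a=5e5 a.u., k1=0.2 s^-1, b=114 a.u."""
    t = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    a, k1, b = 5e5, 0.2, 114.0
    return t, a * np.exp(-k1 * t) + b, (a, k1, b)
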