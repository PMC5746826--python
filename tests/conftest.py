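import math

import numpy as np
import pytest

from fiberweb.network import RVENetwork


@pytest.fixture
def single_fiber_network():
    """One fiber through the middle of a small field, angle configurable."""

    def make(alpha: float, field_mm: float = 0.00512, length_factor: float = 1.3):
        return RVENetwork(
            L=field_mm,
            T=1.0,
            r=1.0e-4,
            seed=0,
            x=np.array([field_mm / 2]),
            y=np.array([field_mm / 2]),
            alpha=np.array([float(alpha) % math.pi]),
            length=np.array([field_mm * length_factor]),
            strip_u=np.array([0.5]),
        )

    return make
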