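import numpy as np
import pytest

from chemorace.theory_core import MotilityParams, ResponseKernel


@pytest.fixture
def motility() -> MotilityParams:
    """Wild-type-like motility: u=15 μm/s, tau_r=1.15 s, Drot=0.1, <cos phi>=0.3."""
    return MotilityParams()


@pytest.fixture
def adapted_kernel() -> ResponseKernel:
    return ResponseKernel(K0=1.0, lam=1.0, A=0.0)


@pytest.fixture
def serine_kernel() -> ResponseKernel:
    """Non-adapted response: lobe imbalance A=0.03 measured for serine."""
    return ResponseKernel(K0=1.0, lam=1.0, A=0.03)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
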