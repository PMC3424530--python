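import numpy as np
import pytest
from hypothesis import settings

from stdpsync import (
    DoubletKernelParams,
    get_preset,
)

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def vc_doublet() -> DoubletKernelParams:
    """Realistic doublet fit (visual cortex pairing data)."""
    return get_preset("visual_cortex_doublet")


@pytest.fixture
def symmetric_doublet() -> DoubletKernelParams:
    """Fully symmetric kernel: odd in the lag, zero integral."""
    return DoubletKernelParams(0.01, 0.01, 20.0, 20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_kernel(rng: np.random.Generator) -> DoubletKernelParams:
    """Random but physiologically shaped doublet kernel for property tests."""
    return DoubletKernelParams(
        a_plus=float(rng.uniform(1e-3, 0.05)),
        a_minus=float(rng.uniform(1e-3, 0.05)),
        tau_plus=float(rng.uniform(2.0, 60.0)),
        tau_minus=float(rng.uniform(2.0, 60.0)),
    )
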