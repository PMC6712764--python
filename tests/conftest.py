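import pytest

from tumorvox import (
    LatticeSpec,
    sample_anisotropic_kernel,
    sample_isotropic_kernel,
)
from tumorvox.engine import default_cell_tensor


@pytest.fixture(scope="session")
def spec5():
    return LatticeSpec(N=5, delta_s=2.0, delta_tau=10.0)


@pytest.fixture(scope="session")
def oxygen_kernel(spec5):
    # modest sample count: unit tests only need a well-formed kernel
    return sample_isotropic_kernel(1.8e-5, spec5, n_samples=200_000, seed=7)


@pytest.fixture(scope="session")
def cell_kernel(spec5):
    return sample_anisotropic_kernel(default_cell_tensor(), spec5,
                                     n_samples=200_000, seed=8)
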