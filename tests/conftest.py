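import numpy as np
import pytest

from intflex import synthetic
from intflex.model import scale_offdiagonal, set_recurrent


@pytest.fixture(scope="session")
def small_connectome() -> np.ndarray:
    """Scaled 24-region synthetic coupling matrix with default recurrence."""
    W = synthetic.gen_connectome(synthetic.ConnectomeSpec(n_regions=24, seed=5))
    return set_recurrent(scale_offdiagonal(W), 1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
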