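import numpy as np
import pytest

from surrqa import gen_ar2ns, gen_ar2s


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ar2s_series():
    return gen_ar2s(seed=0)


@pytest.fixture(scope="session")
def ar2ns_series():
    return gen_ar2ns(seed=0)


def random_binary_matrix(seed: int, n: int = 30, density: float = 0.3) -> np.ndarray:
    """Seeded random RP-like binary matrix with the LOI set."""
    rng = np.random.default_rng(seed)
    mat = rng.random((n, n)) < density
    np.fill_diagonal(mat, True)
    return mat
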