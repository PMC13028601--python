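import numpy as np
import pytest

from srca import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_sphere():
    """Noiseless sphere on coordinates {1,3,4} of a 6-dim space."""
    rng = np.random.default_rng(0)
    c0 = rng.uniform(-1.0, 1.0, 6)
    return synthetic.sample_subsphere(
        n=120, d=6, index_set=[1, 3, 4], center=c0, radius=1.5,
        noise_sd=0.0, seed=0)


@pytest.fixture
def noisy_sphere():
    rng = np.random.default_rng(7)
    c0 = rng.uniform(-1.0, 1.0, 5)
    return synthetic.sample_subsphere(
        n=150, d=5, index_set=[0, 1, 2], center=c0, radius=2.0,
        noise_sd=0.1, seed=7)


def random_orthogonal(d, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, d))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))
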