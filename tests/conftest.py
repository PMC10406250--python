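import numpy as np
import pytest

from aniso4d import PhantomSpec, build_canonical_hrf, synthesize


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def kernel():
    """Canonical double-gamma kernel at TR 1 s."""
    return build_canonical_hrf(tr=1.0)


@pytest.fixture(scope="session")
def tiny_phantom(kernel):
    """Small noisy block phantom for fast end-to-end checks."""
    spec = PhantomSpec(shape=(6, 6, 6), duration=60.0, blocks=((15.0, 35.0, 1.0),),
                       sigma_a=0.3, seed=7)
    return synthesize(spec, kernel)


def toeplitz_operator(samples: np.ndarray, n: int) -> np.ndarray:
    """Dense lower-triangular Toeplitz matrix of causal convolution.

    Independent oracle for the HRF operators: H[i, j] = h[i − j].
    """
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(max(0, i - samples.size + 1), i + 1):
            H[i, j] = samples[i - j]
    return H
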