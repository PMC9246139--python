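import numpy as np
import pytest

from clustsim import ScenarioSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_blob_data(rng):
    """Two tight, well-separated spherical blobs in 2-D (n=40)."""
    a = rng.normal(0.0, 0.05, size=(20, 2))
    b = rng.normal(8.0, 0.05, size=(20, 2))
    x = np.vstack([a, b])
    labels = np.repeat([1, 2], 20)
    return x, labels


@pytest.fixture
def homogeneous_dataset(rng):
    """One-group cohort, 3 near-orthogonal indicators, N=300."""
    spec = ScenarioSpec(p=3, n=300, true_k=1, rho_range=(-0.02, 0.02), label="homog")
    return generate_dataset(spec, rng)
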