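import numpy as np
import pytest

from sfdikit.light_transport import build_lut
from sfdikit.spectral import load_default_basis


@pytest.fixture(scope="session")
def basis():
    return load_default_basis()


@pytest.fixture(scope="session")
def default_lut():
    return build_lut()


@pytest.fixture(scope="session")
def frequencies():
    return np.linspace(0.0, 0.33, 30)


def gaussian_classes(n_classes, n_per_class, dim, sep, seed, sd=1.0):
    """Balanced Gaussian blobs with class means ``sep`` pooled-SDs apart along axes."""
    rng = np.random.default_rng(seed)
    feats = []
    labels = []
    for c in range(n_classes):
        mean = np.zeros(dim)
        mean[c % dim] = sep * sd * (1 + c // dim)
        feats.append(mean + sd * rng.standard_normal((n_per_class, dim)))
        labels.extend([f"C{c}"] * n_per_class)
    return np.vstack(feats), np.asarray(labels)
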