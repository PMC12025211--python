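import numpy as np
import pytest

from ctbalance.phantom import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def tiny_params() -> PhantomParams:
    return PhantomParams(image_size=32, slices_per_patient=20, l3_fraction=0.05, seed=123)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    """Eight small phantom patients shared across tests (read-only)."""
    return generate_cohort(tiny_params, 8, seed=123)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_masks(rng: np.random.Generator, n: int, size: int = 16, n_classes: int = 5):
    """Pairs of random label masks biased to contain some empty classes."""
    pairs = []
    for _ in range(n):
        a = rng.integers(0, n_classes, size=(size, size))
        b = rng.integers(0, n_classes, size=(size, size))
        if rng.random() < 0.2:  # occasionally drop a class entirely
            drop = int(rng.integers(1, n_classes))
            a[a == drop] = 0
        pairs.append((a, b))
    return pairs
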