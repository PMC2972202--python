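import itertools

import numpy as np
import pytest

from rarecomb import (
    GenotypeMatrix,
    PhenotypeVector,
    generate_haplotype_pool,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pool():
    """A default synthetic haplotype pool, shared across tests."""
    return generate_haplotype_pool(seed=7)


@pytest.fixture
def toy_case_control():
    """4 individuals x 3 variants: v1, v2 carried only by cases, v3 only by
    controls."""
    dosages = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 0],
        ]
    )
    G = GenotypeMatrix.from_dosages(dosages, ["v1", "v2", "v3"])
    Y = PhenotypeVector.from_values([1, 1, 0, 0])
    return G, Y


def random_dataset(rng, n=30, p=5, dichotomous=True):
    """A random small polymorphic dataset for property checks."""
    while True:
        dos = rng.binomial(2, rng.uniform(0.05, 0.4, size=p), size=(n, p))
        if (dos.sum(axis=0) > 0).all() and (dos < 2).any(axis=0).all():
            break
    G = GenotypeMatrix.from_dosages(dos, [f"v{j}" for j in range(p)])
    if dichotomous:
        while True:
            y = rng.integers(0, 2, size=n).astype(float)
            if 0 < y.sum() < n:
                break
        Y = PhenotypeVector.from_values(y)
    else:
        Y = PhenotypeVector.from_values(rng.standard_normal(n), "continuous")
    return G, Y
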