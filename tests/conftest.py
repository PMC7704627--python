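import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import promotif as pm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def matrices():
    return pm.example_matrices()


@pytest.fixture(scope="session")
def gabpa(matrices):
    return matrices[0]


@pytest.fixture(scope="session")
def effect_study(matrices):
    """14/14 study with the GABPA-like motif favouring active promoters."""
    return pm.generate_study(pm.effect_config(seed=42), matrices)


def random_matrix(rng, length=None, matrix_id="RAND"):
    """A random, non-degenerate count matrix for oracle comparisons."""
    length = length or int(rng.integers(5, 13))
    while True:
        counts = rng.integers(0, 21, size=(length, 4)).astype(float)
        counts[rng.integers(0, length)] = [20, 0, 0, 0]  # ensure informative
        if np.all(counts.sum(axis=1) > 0):
            return pm.FrequencyMatrix(matrix_id=matrix_id, counts=counts)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
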