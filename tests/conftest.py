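import numpy as np
import pytest

from tmea import (
    AbundanceMatrix,
    decompose,
    log_transform,
    make_truth,
    synthesize_matrix,
)


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    rng = np.random.default_rng(7)
    values = np.exp(rng.normal(loc=3.0, scale=1.0, size=(6, 4)))
    return AbundanceMatrix(
        [f"E{i}" for i in range(6)], [f"t{j}" for j in range(4)], values
    )


@pytest.fixture
def small_decomposition(small_matrix):
    return decompose(log_transform(small_matrix, 0.0))


@pytest.fixture(scope="session")
def synthetic_study():
    """A desk-scale synthetic time course with its decomposition."""
    truth = make_truth(n_entities=600, n_conditions=11, rank=3, seed=11)
    matrix = synthesize_matrix(truth, seed=12)
    decomp = decompose(log_transform(matrix, 0.0))
    return truth, matrix, decomp
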