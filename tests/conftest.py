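import numpy as np
import pytest

from dendroheat import BlobSpec, DataMatrix, make_blobs, make_document, make_metadata


@pytest.fixture
def small_data() -> DataMatrix:
    """Deterministic 6x3 matrix with two well-separated groups of rows."""
    values = np.array(
        [
            [0.0, 0.1, 0.2],
            [0.1, 0.0, 0.3],
            [0.2, 0.1, 0.1],
            [10.0, 10.2, 9.9],
            [10.1, 9.8, 10.0],
            [9.9, 10.1, 10.2],
        ]
    )
    return DataMatrix([f"c{i}" for i in range(6)], ["logP", "TPSA", "MW"], values)


@pytest.fixture
def blob_data():
    return make_blobs(BlobSpec(n_rows=20, n_features=4, n_clusters=3, seed=7))


@pytest.fixture
def pipeline_document():
    return make_document(BlobSpec(n_rows=15, n_features=4, n_clusters=3, seed=11))


def random_matrix(rng: np.random.Generator, n: int, m: int) -> DataMatrix:
    return DataMatrix(
        [f"r{i}" for i in range(n)],
        [f"f{j}" for j in range(m)],
        rng.normal(size=(n, m)),
    )
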