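import numpy as np
import pandas as pd
import pytest

from hoodspot.lattice import SpatialWeights, build_weights, make_hex_grid


@pytest.fixture(scope="session")
def grid10():
    return make_hex_grid(10, 10)


@pytest.fixture(scope="session")
def weights10(grid10):
    return build_weights(grid10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def manual_weights(neighbors):
    """Row-standardized weights from an explicit neighbor-list dict/list."""
    nbrs = [np.array(sorted(nb), dtype=int) for nb in neighbors]
    wts = [np.full(len(nb), 1.0 / len(nb)) if len(nb) else np.array([]) for nb in nbrs]
    islands = np.array([i for i, nb in enumerate(nbrs) if len(nb) == 0], dtype=int)
    return SpatialWeights(
        neighbors=nbrs,
        weights=wts,
        barcodes=pd.Series([f"s{i}" for i in range(len(nbrs))]),
        islands=islands,
    )


@pytest.fixture
def cycle4():
    return manual_weights([[1, 3], [0, 2], [1, 3], [0, 2]])


@pytest.fixture
def path6():
    return manual_weights([[1], [0, 2], [1, 3], [2, 4], [3, 5], [4]])
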