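import numpy as np
import pytest

from steer.io_data import VelocityDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_dataset(rng):
    """10 cells × 5 genes of small integer counts."""
    U = rng.integers(0, 20, size=(10, 5)).astype(float)
    S = rng.integers(0, 30, size=(10, 5)).astype(float)
    return VelocityDataset(
        U=U,
        S=S,
        gene_names=np.array([f"g{j}" for j in range(5)]),
        cell_ids=np.array([f"c{i}" for i in range(10)]),
    )


def make_dataset(U, S, coords=None, labels=None):
    n, g = np.asarray(U).shape
    return VelocityDataset(
        U=np.asarray(U, dtype=float),
        S=np.asarray(S, dtype=float),
        gene_names=np.array([f"g{j}" for j in range(g)]),
        cell_ids=np.array([f"c{i}" for i in range(n)]),
        spatial_coords=coords,
        cell_labels=labels,
    )
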