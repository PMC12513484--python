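import numpy as np
import pytest
from scipy import sparse

from orgspatial import MarkerPanel, SpatialDataset
from orgspatial.simulate import fixture_small


@pytest.fixture(scope="session")
def fixture_data():
    """The reference synthetic dataset (~400 cells, 60 genes) with truth."""
    return fixture_small()


@pytest.fixture()
def toy_dataset():
    """3 cells x 4 genes, two samples, two conditions, hand-checkable."""
    counts = np.array(
        [
            [1, 0, 2, 0],
            [0, 3, 0, 1],
            [5, 0, 0, 0],
        ]
    )
    return SpatialDataset(
        cell_ids=["c1", "c2", "c3"],
        x=[0.0, 3.0, 10.0],
        y=[0.0, 4.0, 0.0],
        sample_id=["s1", "s1", "s2"],
        condition=["control", "control", "MCT8"],
        counts=sparse.csr_matrix(counts),
        gene_ids=["VIM", "EOMES", "GATA3", "G1"],
    )


@pytest.fixture()
def panel():
    return MarkerPanel()
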