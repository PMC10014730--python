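import numpy as np
import pytest
import scipy.sparse as sp

from atacml import AccessibilityDataset, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def benchmark():
    """The 8-class planted-marker benchmark: 150 cells/class, 500 genes,
    5 disjoint markers per class, p_on 0.9, p_bg 0.1, no flips, seed 1."""
    cfg = SyntheticConfig(
        n_classes=8,
        class_sizes=(150,) * 8,
        n_genes=500,
        markers_per_class=5,
        p_on=0.9,
        p_bg=0.1,
        flip_rate=0.0,
        seed=1,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable():
    """Perfectly separable toy: markers deterministic, no background."""
    cfg = SyntheticConfig(
        n_classes=4,
        class_sizes=(30,) * 4,
        n_genes=60,
        markers_per_class=2,
        p_on=1.0,
        p_bg=0.0,
        flip_rate=0.0,
        seed=11,
    )
    return generate_dataset(cfg)


def make_dataset(X, labels, kind="binary"):
    """Wrap a dense array and labels into a dataset with default ids."""
    X = np.asarray(X, dtype=float)
    return AccessibilityDataset(
        matrix=sp.csr_matrix(X),
        cell_ids=[f"c{i:04d}" for i in range(X.shape[0])],
        cell_types=[str(l) for l in labels],
        gene_ids=[f"g{j:04d}" for j in range(X.shape[1])],
        kind=kind,
    )
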