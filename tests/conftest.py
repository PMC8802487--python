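import numpy as np
import pytest

from cyclepos import (
    GeneExpressionMatrix,
    learn_reference,
    simulate_cosine_gaussian,
)
from cyclepos.simulate import two_family_config


@pytest.fixture
def toy_counts() -> GeneExpressionMatrix:
    """Small deterministic count matrix: 10 genes x 5 cells.

    Cell 'c2' expresses exactly one gene; all other cells express >= 3.
    """
    rng = np.random.default_rng(7)
    counts = rng.poisson(5, size=(10, 5)) + 1  # no zeros: every gene expressed
    counts[:, 2] = 0
    counts[0, 2] = 4  # cell index 2 expresses exactly 1 gene
    return GeneExpressionMatrix(
        values=counts,
        cell_ids=np.array([f"c{i}" for i in range(5)], dtype=object),
        gene_ids=np.array([f"ENSG{i:03d}" for i in range(10)], dtype=object),
        gene_symbols=np.array([f"Gene{i}" for i in range(10)], dtype=object),
        value_kind="counts",
    )


@pytest.fixture(scope="session")
def gaussian_sim():
    """Canonical two-family cosine simulation (100 genes x 1000 grid cells)."""
    return simulate_cosine_gaussian(two_family_config(seed=11))


@pytest.fixture(scope="session")
def gaussian_ref(gaussian_sim):
    return learn_reference(
        gaussian_sim.matrix, list(gaussian_sim.matrix.gene_keys()), source="test"
    )
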