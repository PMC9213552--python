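import numpy as np
import pytest

from icmcoord import ExpressionMatrix, RegimeConfig, simulate_regime


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, assay="normalized", mask=None, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(values=values, mask=np.asarray(mask, bool),
                            assay=assay, gene_ids=genes, cell_ids=cells)


@pytest.fixture(scope="session")
def coordinated_dataset():
    """One coordinated-regime draw under the default study conditions."""
    return simulate_regime(RegimeConfig(seed=424242))


@pytest.fixture(scope="session")
def independent_dataset():
    return simulate_regime(RegimeConfig(seed=424243, regime="independent"))
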