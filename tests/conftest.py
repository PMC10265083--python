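import numpy as np
import pandas as pd
import pytest

from spermatocap import core, datasets, synthetic


def make_norm(values, genes=None, cells=None, donor=None, group=None, cell_type=None):
    """Build a NormalizedMatrix directly from a dense array for toy tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = list(genes) if genes is not None else [f"G{i}" for i in range(n_genes)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta["donor"] = donor if donor is not None else "d1"
    meta["group"] = group if group is not None else "NC"
    if cell_type is not None:
        meta["cell_type"] = cell_type
    return core.NormalizedMatrix(
        values=values, gene_symbols=np.asarray(genes, dtype=object),
        cell_ids=np.asarray(cells, dtype=object), cell_meta=meta,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across the suite."""
    matrix, truth = synthetic.generate_dataset(synthetic.SimConfig(seed=1))
    return matrix, truth


@pytest.fixture(scope="session")
def default_norm(default_dataset):
    matrix, _ = default_dataset
    return core.normalize(matrix)


@pytest.fixture(scope="session")
def truth_cells(default_dataset):
    _, truth = default_dataset
    return truth.cells.set_index("cell_id")


@pytest.fixture(scope="session")
def germ_cell_ids(truth_cells):
    return list(truth_cells.index[truth_cells["cell_type"].isin(datasets.STAGE_ORDER)])
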