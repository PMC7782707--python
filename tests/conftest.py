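import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from popsc.config import PipelineConfig
from popsc.matrix import UmiMatrix
from popsc.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def tiny_umi(counts, genes=None, cells=None, conditions=None, samples=None, types=None):
    """Hand-built UmiMatrix from a dense array (genes x cells)."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{j}" for j in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample": samples or ["S1"] * n_cells,
            "condition": conditions or ["control"] * n_cells,
        },
        index=pd.Index(cells, name="cell"),
    )
    if types is not None:
        meta["cell_type"] = types
    return UmiMatrix(
        counts=sp.csr_matrix(counts), gene_ids=genes, cell_ids=cells, cell_meta=meta
    )


@pytest.fixture(scope="session")
def desk_sim():
    """Desk-scale default simulation shared across read-only tests."""
    return simulate(SimulationSpec(rng_seed=3))


@pytest.fixture(scope="session")
def null_sim():
    """Simulation with no planted structure at all (fully exchangeable cells)."""
    spec = SimulationSpec(
        planted_degs=(), planted_lr=(), markers_per_type=0, qc_outliers={}, rng_seed=8
    )
    return simulate(spec)
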