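import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from trajde.data import CellExperiment
from trajde.binning import squeeze
from trajde.simulate import SimConfig, simulate_bifurcation


@pytest.fixture
def toy_experiment():
    """3 genes x 8 cells, two paths with 4 cells each."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(5, size=(3, 8))
    return CellExperiment(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"g{i}" for i in range(3)],
        cell_ids=[f"c{i}" for i in range(8)],
        pseudotime=np.array([0.0, 1.0, 2.0, 3.0, 0.0, 1.0, 2.0, 3.0]),
        path=np.array(["A"] * 4 + ["B"] * 4, dtype=object),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated bifurcation with ground truth."""
    config = SimConfig(n_genes=300, n_cells=1200, seed=11)
    return simulate_bifurcation(config)


@pytest.fixture(scope="session")
def small_binned(small_sim):
    experiment, _ = small_sim
    return squeeze(experiment)


def two_path_meta(n_bins=13):
    """Balanced two-path bin metadata with unit offsets for GLM tests."""
    meta = pd.DataFrame(
        {
            "t_index": list(range(1, n_bins + 1)) * 2,
            "path": ["A"] * n_bins + ["B"] * n_bins,
        }
    )
    meta["offset"] = 0.0
    return meta
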