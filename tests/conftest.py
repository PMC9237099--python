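import numpy as np
import pandas as pd
import pytest

from commtensor import (
    CellTypeProfile,
    LRCatalog,
    LRPair,
    SimTruth,
    build_simulated_tensor,
    nncp_als,
)


@pytest.fixture(scope="session")
def sim_system():
    """Noiseless simulated tensor with the default study design."""
    truth = SimTruth(seed=0)
    tensor, truth = build_simulated_tensor(truth)
    return tensor, truth


@pytest.fixture(scope="session")
def sim_fit(sim_system):
    """Rank-4 decomposition of the noiseless simulated tensor, normalized."""
    tensor, truth = sim_system
    return nncp_als(tensor, 4, seed=0).normalized(), truth


@pytest.fixture
def small_profiles():
    """Two tiny contexts with overlapping genes and cell types."""
    genes = ["L1", "L2", "R1", "R2", "G5"]
    p1 = CellTypeProfile(
        context_id="ctx1",
        values=pd.DataFrame(
            [[0.2, 0.8, 0.5, 0.1, 0.0], [0.6, 0.4, 0.9, 0.3, 0.2]],
            index=["A", "B"],
            columns=genes,
        ),
        aggregation="nonzero_fraction",
    )
    p2 = CellTypeProfile(
        context_id="ctx2",
        values=pd.DataFrame(
            [[0.1, 0.5, 0.4, 0.6, 0.3], [0.7, 0.2, 0.8, 0.9, 0.1]],
            index=["A", "B"],
            columns=genes,
        ),
        aggregation="nonzero_fraction",
    )
    return [p1, p2]


@pytest.fixture
def small_catalog():
    return LRCatalog(
        [
            LRPair("L1^R1", ("L1",), ("R1",)),
            LRPair("L1&L2^R2", ("L1", "L2"), ("R2",)),
        ]
    )


def random_results(rng, shape=(4, 5, 3, 3), rank=3):
    """A random valid decomposition results object over integer labels."""
    from commtensor.decompose import CPResults, DIM_NAMES

    factors = {
        name: pd.DataFrame(
            rng.random((dim, rank)) + 0.01,
            index=[f"{name[:3]}{i}" for i in range(dim)],
            columns=[f"factor_{r + 1}" for r in range(rank)],
        )
        for name, dim in zip(DIM_NAMES, shape)
    }
    return CPResults(
        tensor=None,
        rank=rank,
        factors=factors,
        norm_error=0.5,
        seed=0,
        n_iter_run=1,
    )


@pytest.fixture
def results_factory():
    return random_results
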