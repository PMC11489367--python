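import numpy as np
import pytest

from ripopgen.genotype_io import GenotypeMatrix, PopulationMeta, PopulationSet
from ripopgen.synthetic_data import SimulationConfig, simulate_mixed_mating_population


def make_matrix(calls, individual_ids=None, locus_ids=None):
    """Build a GenotypeMatrix from a nested list of (a, b) pairs."""
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    return GenotypeMatrix(
        individual_ids or [f"i{k}" for k in range(n)],
        locus_ids or [f"L{j}" for j in range(L)],
        calls,
    )


@pytest.fixture
def two_pop_set():
    a = make_matrix([[(1, 1), (3, 4)], [(1, 2), (3, 3)], [(2, 2), (4, 4)]])
    b = make_matrix([[(1, 2), (3, 4)], [(2, 2), (4, 4)], [(1, 1), (3, 3)]])
    return PopulationSet(
        {"P1": a, "P2": b},
        {"P1": PopulationMeta(type="sympatric", x_km=0.0, y_km=0.0),
         "P2": PopulationMeta(type="allopatric", x_km=3.0, y_km=4.0)},
    )


@pytest.fixture(scope="session")
def sim_pop_seed3():
    """Random-mating simulated population reused by the tally-oracle tests."""
    cfg = SimulationConfig(N=100, s=0.0, L=5, k=6, mu=1e-3, G=20, seed=3,
                           sample_size=40)
    return simulate_mixed_mating_population(cfg)
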