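import numpy as np
import pandas as pd
import pytest

from popadapt import (
    GenotypeMatrix, SimConfig, compute_grm, sim_island_genotypes,
)


@pytest.fixture(scope="session")
def island_panel():
    """A small structured island panel with its truth (shared, read-only)."""
    cfg = SimConfig(n_pops=4, n_per_pop=50, n_loci=800, target_fst=0.05, seed=7)
    g, truth = sim_island_genotypes(cfg)
    return g, truth, cfg


@pytest.fixture(scope="session")
def island_grm(island_panel):
    g, truth, cfg = island_panel
    return compute_grm(g)


@pytest.fixture()
def tiny_genotypes():
    """Hand-sized genotype matrix for exact-value tests."""
    dosage = np.array([
        [0, 1, 2, 0],
        [2, 1, 0, 1],
        [1, 0, 1, 2],
        [1, 2, 1, 0],
        [0, 1, 2, 1],
        [2, 0, 0, 2],
    ], dtype=float)
    loci = pd.DataFrame({"id": [f"L{j}" for j in range(4)],
                         "chrom": [1, 1, 2, 2], "pos": [10, 20, 10, 20]})
    return GenotypeMatrix(dosage=dosage, loci=loci,
                          samples=[f"s{i}" for i in range(6)])
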