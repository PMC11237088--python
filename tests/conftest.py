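import numpy as np
import pytest

from cellink.synth import SimConfig, sim_cells, sim_genotypes


@pytest.fixture(scope="session")
def small_geno():
    """50 donors x 30 variants, moderate LD, no missingness."""
    return sim_genotypes(SimConfig(n_donors=50, n_variants=30, seed=42))


@pytest.fixture(scope="session")
def small_cells():
    """~1.5k cells from 12 donors with a planted subpopulation and 10%
    planted QC violations."""
    cfg = SimConfig(n_donors=12, n_genes=200, n_cells_per_donor=(100, 140), seed=7)
    return sim_cells(
        cfg, {"AD": 0.3, "CT": 0.05}, qc_violation_frac=0.1, mean_umi=3000.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
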