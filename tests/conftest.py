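import numpy as np
import pytest

from medscan.genio import GenotypeMatrix
from medscan.syndata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_panel():
    """100 accessions x 800 markers, 3 subpopulations, FST 0.10."""
    cfg = SimConfig(n_accessions=100, n_markers=800, fst=0.10, seed=11)
    return simulate_population(cfg)


@pytest.fixture
def toy_genotypes():
    """Hand-written 5 x 8 matrix with one missing call."""
    calls = np.array([
        [0, 1, 2, 0, 1, 2, 0, 1],
        [0, 1, 2, 0, 1, 2, 0, 1],
        [2, 1, 0, 2, 1, 0, 2, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [0, 0, 0, 2, 2, 2, -1, 0],
    ], dtype=np.int8)
    return GenotypeMatrix(
        accession_ids=[f"a{i}" for i in range(1, 6)],
        marker_ids=[f"m{j}" for j in range(1, 9)],
        calls=calls,
        alleles=[("A", "G")] * 8,
    )
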