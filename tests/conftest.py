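import numpy as np
import pytest

from invscan.genotype_io import ChromosomeTable, GenotypeMatrix
from invscan.simulate import (InversionSpec, SimulationConfig,
                              chrom_table_for, simulate_dataset)


def make_gm(dosage, pos=None, chrom="1", sample_ids=None) -> GenotypeMatrix:
    """Build a single-chromosome GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.full(m, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "T", dtype=object),
        dosage=dosage,
    )


@pytest.fixture
def gm_factory():
    return make_gm


# a compact simulated inversion dataset shared by several module tests:
# strong divergence so single-seed checks are stable
SMALL_SIM = SimulationConfig(
    n_samples=120,
    chrom="2",
    chrom_length_bp=3_000_000,
    snp_density_per_kb=2.0,
    inversions=[InversionSpec(800_000, 2_200_000, freq=0.3,
                              divergence=0.6, fst_drift=0.2)],
    genotype_error_rate=0.05,
    seed=2024,
)


@pytest.fixture(scope="session")
def small_sim():
    gm, truth = simulate_dataset(SMALL_SIM)
    return gm, truth, chrom_table_for(SMALL_SIM), SMALL_SIM
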