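import numpy as np
import pytest

from popflow.matrix import MISSING, GenotypeMatrix
from popflow.synthetic_data import SimulationConfig, simulate


def make_matrix(dosage, pops=None, chrom=None, pos=None, alleles=None):
    """Small hand-built GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pops is None:
        pops = ["POP1"] * n
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = (np.arange(m) + 1) * 1000
    if alleles is None:
        alleles = np.tile(np.asarray(["A", "G"], dtype=object), (m, 1))
    return GenotypeMatrix(
        sample_ids=np.asarray([f"S{i + 1}" for i in range(n)], dtype=object),
        pop_labels=np.asarray(pops, dtype=object),
        marker_ids=np.asarray([f"m{j + 1}" for j in range(m)], dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        pos_bp=np.asarray(pos, dtype=np.int64),
        alleles=alleles,
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def three_pop_sim():
    """Three drifted populations at linkage equilibrium (F = 0.1)."""
    cfg = SimulationConfig(
        n_pops=3,
        n_per_pop=30,
        n_markers=1500,
        fst_per_pop=(0.1, 0.1, 0.1),
        founder_haplotypes_per_block=None,
        block_length=1,
        missing_rate=0.0,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def block_sim():
    """Single population with 4-founder LD blocks of 50 markers."""
    cfg = SimulationConfig(
        n_pops=1,
        n_per_pop=200,
        n_markers=600,
        fst_per_pop=(0.1,),
        block_length=50,
        founder_haplotypes_per_block=4,
        missing_rate=0.0,
        seed=5,
    )
    return simulate(cfg)
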