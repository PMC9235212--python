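import numpy as np
import pytest

from ldhet import GenotypePanel, simulate_genotypes


def make_panel(dosages, positions=None, chromosomes=None):
    """Small hand-built panel helper used across test modules."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if chromosomes is None:
        chromosomes = np.ones(m, dtype=int)
    return GenotypePanel(
        dosages=dosages,
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chromosomes=np.asarray(chromosomes),
        positions=np.asarray(positions),
        individual_ids=np.array([f"i{i}" for i in range(n)], dtype=object),
    )


@pytest.fixture(scope="session")
def small_panel():
    """Session-wide simulated panel: 150 individuals, 600 SNPs, 2 chromosomes."""
    return simulate_genotypes(
        n_individuals=150, n_snps=600, n_chromosomes=2, chrom_length=6_000_000,
        block_length_range=(20_000, 300_000), within_block_corr_range=(0.2, 0.95),
        maf_range=(0.05, 0.5), seed=314,
    )


@pytest.fixture(scope="session")
def random_dosage_rng():
    return np.random.default_rng(2718)
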