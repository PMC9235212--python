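"""Synthetic genotype panels with regional LD heterogeneity, and trait simulation.

The genotype simulator emulates the salient features of a dense livestock SNP
panel without any demographic model: haplotypes are generated per chromosome
as a first-order two-state Markov chain over SNPs, organised in haplotype
blocks. Within a block, the correlation between adjacent SNP alleles on a
haplotype is a constant ρ drawn once per block; across block boundaries the
correlation is zero. All SNPs in a block share the block's allele frequency,
which makes the Markov transition probabilities exact for any ρ ∈ [0, 1) and
gives an adjacent-SNP dosage r² of ρ². Because both block length and ρ vary
along the genome, the regional mean LD score varies severalfold — the
experimental variable under study.

Quantitative traits follow the equal-heritability-contribution scheme:
``m`` causal SNPs each receive an allele-substitution effect
``a_i = (2 p_i (1 - p_i))^(-1/2) · δ_g / sqrt(m)`` with
``δ_g = sqrt(δ_p² · h²)``, so every causal variant contributes exactly
``δ_g² / m`` to the genetic variance; environmental noise is
``N(0, (1 - h²) δ_p²)`` and the phenotype is their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel

TAGGING_CLASSES = ("very_weak", "weak", "average", "strong", "very_strong")


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulation scenario."""

    tagging_class: str = "average"
    n_causal: int = 100
    h2: float = 0.8
    var_p: float = 1.0
    panel_density: str = "high"
    remove_causal_from_panel: bool = False
    seed: int = 0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.tagging_class not in TAGGING_CLASSES:
            raise ValueError(f"unknown tagging class {self.tagging_class!r}")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must be in (0, 1]")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")
        if self.var_p <= 0:
            raise ValueError("phenotypic variance must be positive")


@dataclass
class SimulatedTrait:
    """Phenotypes, true genetic values and the causal architecture behind them."""

    phenotype: np.ndarray
    tbv: np.ndarray
    causal_indices: np.ndarray
    effects: np.ndarray
    environment: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.environment is None:
            self.environment = self.phenotype - self.tbv


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_individuals: int = 1000,
    n_snps: int = 10_000,
    n_chromosomes: int = 3,
    chrom_length: int = 25_000_000,
    block_length_range: tuple[int, int] = (10_000, 500_000),
    within_block_corr_range: tuple[float, float] = (0.3, 0.99),
    maf_range: tuple[float, float] = (0.01, 0.5),
    region_length_range: tuple[int, int] = (1_000_000, 5_000_000),
    rho_jitter: float = 0.05,
    seed: int = 0,
) -> GenotypePanel:
    """Simulate a diploid dosage panel with block-structured, regionally
    coherent LD.

    Two independent haplotypes per individual are generated per chromosome as
    a block Markov chain (see module docstring) and summed to dosages. SNP
    positions are uniform random within each chromosome, then sorted; block
    boundaries are laid down in bp, so the number of SNPs per block varies
    with local SNP density.

    LD intensity is regionally coherent, as in real genomes where high- and
    low-LD *regions* span many haplotype blocks: each chromosome is tiled
    with LD regions of ``region_length_range`` bp whose base correlation is
    drawn from ``within_block_corr_range``; every block inside a region gets
    the region's base correlation plus an independent ±``rho_jitter``
    perturbation (clipped back to the configured range). Set
    ``region_length_range`` at or below ``block_length_range`` to recover
    independent per-block correlations.
    """
    if chrom_length <= 0 or n_snps <= 0 or n_individuals <= 0:
        raise ValueError("dimensions must be positive")
    lo_b, hi_b = block_length_range
    if not (0 < lo_b <= hi_b <= chrom_length):
        raise ValueError("invalid block length range")
    lo_r, hi_r = within_block_corr_range
    if not (0.0 <= lo_r <= hi_r < 1.0):
        raise ValueError("within-block correlation must lie in [0, 1)")
    lo_p, hi_p = maf_range
    if not (0.0 < lo_p <= hi_p <= 0.5):
        raise ValueError("MAF range must lie in (0, 0.5]")

    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1

    dosage_cols, chroms, positions = [], [], []
    for c in range(n_chromosomes):
        m_c = int(per_chrom[c])
        pos = np.sort(rng.choice(chrom_length, size=m_c, replace=False)) + 1

        # block boundaries along the chromosome in bp
        starts = [0]
        while starts[-1] < chrom_length:
            starts.append(starts[-1] + int(rng.integers(lo_b, hi_b + 1)))
        block_of_snp = np.searchsorted(np.array(starts[1:]), pos - 1, side="right")
        n_blocks = int(block_of_snp.max()) + 1 if m_c else 0
        block_starts = np.array(starts[:-1])[: n_blocks]

        # regionally coherent LD intensity: blocks inherit their region's base
        # correlation with a small independent jitter
        lo_reg, hi_reg = region_length_range
        reg_starts = [0]
        while reg_starts[-1] < chrom_length:
            reg_starts.append(reg_starts[-1] + int(rng.integers(lo_reg, max(lo_reg, hi_reg) + 1)))
        region_of_block = np.searchsorted(np.array(reg_starts[1:]), block_starts, side="right")
        region_rho = rng.uniform(lo_r, hi_r, size=int(region_of_block.max()) + 1 if n_blocks else 0)
        block_rho = np.clip(
            region_rho[region_of_block]
            + rng.uniform(-rho_jitter, rho_jitter, size=n_blocks),
            lo_r, hi_r,
        )
        block_maf = rng.uniform(lo_p, hi_p, size=n_blocks)
        # counted-allele frequency: flip a fair coin per block
        block_p = np.where(rng.random(n_blocks) < 0.5, block_maf, 1.0 - block_maf)

        p = block_p[block_of_snp]
        rho = block_rho[block_of_snp]
        new_block = np.empty(m_c, dtype=bool)
        new_block[0] = True
        new_block[1:] = block_of_snp[1:] != block_of_snp[:-1]
        rho = np.where(new_block, 0.0, rho)  # no correlation across boundaries

        # two-state Markov chain, vectorised over 2n haplotypes
        haps = np.empty((2 * n_individuals, m_c), dtype=np.int8)
        u = rng.random((2 * n_individuals, m_c))
        haps[:, 0] = u[:, 0] < p[0]
        for j in range(1, m_c):
            if new_block[j]:
                haps[:, j] = u[:, j] < p[j]
            else:
                # stationary chain with marginal p and lag-1 correlation rho
                p11 = p[j] + rho[j] * (1.0 - p[j])
                p01 = p[j] * (1.0 - rho[j])
                thresh = np.where(haps[:, j - 1] == 1, p11, p01)
                haps[:, j] = u[:, j] < thresh
        dosage_cols.append(haps[:n_individuals] + haps[n_individuals:])
        chroms.append(np.full(m_c, c + 1))
        positions.append(pos)

    panel = GenotypePanel(
        dosages=np.concatenate(dosage_cols, axis=1).astype(float),
        snp_ids=np.array([f"snp{c}_{i}" for c, m in zip(range(1, n_chromosomes + 1), per_chrom)
                          for i in range(int(m))], dtype=object),
        chromosomes=np.concatenate(chroms),
        positions=np.concatenate(positions),
        individual_ids=np.array([f"ind{i}" for i in range(n_individuals)], dtype=object),
    )
    return panel


# ---------------------------------------------------------------------------
# Tagging classes and causal-variant selection
# ---------------------------------------------------------------------------

def classify_tagging(panel: GenotypePanel, ld_scores: np.ndarray) -> dict[str, np.ndarray]:
    """Quantile tagging classes from per-SNP LD scores (Σ_k r²_jk, 10-Mb window).

    Returns index arrays for each class: bottom 20% → ``very_weak``, bottom
    40% → ``weak``, top 40% → ``strong``, top 20% → ``very_strong`` (the
    narrow classes are subsets of the wide ones), and ``average`` = all SNPs.
    Ties are broken by (score, chromosome, position) so class sizes always
    equal the quantile counts.
    """
    m = panel.n_snps
    if m < 5:
        raise ValueError("need at least 5 SNPs to form tagging quantiles")
    if len(ld_scores) != m:
        raise ValueError("ld_scores length mismatch")
    order = np.lexsort((panel.positions, panel.chromosomes, np.asarray(ld_scores)))
    k20, k40 = int(m * 0.2), int(m * 0.4)
    return {
        "very_weak": np.sort(order[:k20]),
        "weak": np.sort(order[:k40]),
        "average": np.arange(m),
        "strong": np.sort(order[m - k40:]),
        "very_strong": np.sort(order[m - k20:]),
    }


def select_causal(
    panel: GenotypePanel,
    tagging: dict[str, np.ndarray],
    tagging_class: str,
    n_causal: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample ``n_causal`` SNP indices uniformly without replacement from a class."""
    if tagging_class not in tagging:
        raise ValueError(f"unknown tagging class {tagging_class!r}")
    pool = tagging[tagging_class]
    if n_causal > len(pool):
        raise ValueError(f"n_causal={n_causal} exceeds class size {len(pool)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return np.sort(rng.choice(pool, size=n_causal, replace=False))


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    panel: GenotypePanel,
    causal_indices: np.ndarray,
    h2: float = 0.8,
    var_p: float = 1.0,
    seed: int | np.random.Generator = 0,
    random_signs: bool = True,
) -> SimulatedTrait:
    """Simulate a trait with equal per-causal heritability contributions.

    Each causal SNP i gets |a_i| = (2 p_i (1-p_i))^(-1/2) · δ_g / sqrt(m) with
    δ_g = sqrt(var_p · h2), so 2 p_i (1-p_i) a_i² = δ_g²/m exactly for every i.
    By default each effect is multiplied by an independent random sign; with
    ``random_signs=False`` all effects are positive. Environmental effects are
    N(0, (1 - h2) · var_p) and the phenotype is tbv + e.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must be in (0, 1]")
    causal_indices = np.asarray(causal_indices)
    p = panel.allele_freq[causal_indices]
    if np.any((p <= 0.0) | (p >= 1.0)) or np.isnan(p).any():
        raise ValueError("causal SNP is monomorphic")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    m = len(causal_indices)
    delta_g = np.sqrt(var_p * h2)
    effects = (2.0 * p * (1.0 - p)) ** -0.5 * delta_g / np.sqrt(m)
    if random_signs:
        effects = effects * rng.choice([-1.0, 1.0], size=m)

    dos = panel.imputed_dosages()[:, causal_indices]
    tbv = dos @ effects
    env = rng.normal(0.0, np.sqrt((1.0 - h2) * var_p), size=panel.n_individuals)
    return SimulatedTrait(
        phenotype=tbv + env,
        tbv=tbv,
        causal_indices=causal_indices,
        effects=effects,
        environment=env,
    )


# ---------------------------------------------------------------------------
# Panel manipulation for the density experiments
# ---------------------------------------------------------------------------

def build_medium_panel(panel: GenotypePanel, target_count: int) -> GenotypePanel:
    """Evenly spaced SNP subset, allocated per chromosome by SNP count.

    The per-chromosome target is proportional to the chromosome's SNP count
    (largest-remainder rounding); within a chromosome, SNPs are taken at
    evenly strided index ranks starting from the first SNP.
    """
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    if target_count > panel.n_snps:
        raise ValueError("target_count exceeds panel size")
    chrom_labels, counts = np.unique(panel.chromosomes, return_counts=True)
    quota = counts * target_count / panel.n_snps
    alloc = np.floor(quota).astype(int)
    remainder = target_count - alloc.sum()
    if remainder > 0:
        top_up = np.argsort(-(quota - alloc))[:remainder]
        alloc[top_up] += 1

    keep = []
    for chrom, k in zip(chrom_labels, alloc):
        idx = np.where(panel.chromosomes == chrom)[0]
        if k == 0:
            continue
        stride = len(idx) // k
        keep.append(idx[::stride][:k] if stride >= 1 else idx[:k])
    return panel.subset_snps(np.sort(np.concatenate(keep)))


def drop_causal(panel: GenotypePanel, causal_indices: np.ndarray) -> GenotypePanel:
    """Panel with the causal SNP columns removed."""
    causal_indices = np.asarray(causal_indices)
    if causal_indices.size and (
        causal_indices.min() < 0 or causal_indices.max() >= panel.n_snps
    ):
        raise IndexError("causal index out of range")
    mask = np.ones(panel.n_snps, dtype=bool)
    mask[causal_indices] = False
    return panel.subset_snps(np.where(mask)[0])
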