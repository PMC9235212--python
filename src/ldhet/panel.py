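"""Core genotype-panel container shared by all modules.

A :class:`GenotypePanel` holds diploid SNP dosages (counts of the A1 allele,
0/1/2, ``NaN`` for missing) for ``n`` individuals at ``m`` autosomal SNPs,
together with per-SNP chromosome, base-pair position and allele frequency.
Positions are 1-based and strictly increasing within each chromosome, as in
PLINK BIM files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class GenotypePanel:
    """Individuals × SNPs dosage matrix with SNP map metadata.

    Parameters
    ----------
    dosages
        ``(n, m)`` float array; entries in {0, 1, 2} or NaN for missing.
        Dosage counts the A1 (counted) allele.
    snp_ids, chromosomes, positions
        Per-SNP identifier, integer chromosome label, 1-based bp position.
    individual_ids
        Per-individual identifiers (unique).
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    individual_ids: np.ndarray
    allele_freq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=int)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, m = self.dosages.shape
        if not (len(self.snp_ids) == len(self.chromosomes) == len(self.positions) == m):
            raise ValueError("SNP metadata length does not match dosage columns")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        for chrom in np.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        valid = self.dosages[~np.isnan(self.dosages)]
        if valid.size and not np.isin(valid, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        if self.allele_freq is None:
            self.allele_freq = self.compute_allele_freq()
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def compute_allele_freq(self) -> np.ndarray:
        """A1 allele frequency per SNP: mean dosage over non-missing, / 2.

        All-missing SNPs get NaN (they are removed by QC).
        """
        present = (~np.isnan(self.dosages)).sum(axis=0)
        totals = np.nansum(self.dosages, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(present > 0, totals / np.maximum(present, 1) / 2.0, np.nan)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    # -- derived views -----------------------------------------------------
    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed to 2·p_j."""
        if not np.isnan(self.dosages).any():
            return self.dosages
        out = self.dosages.copy()
        fill = 2.0 * self.allele_freq
        idx = np.where(np.isnan(out))
        out[idx] = fill[idx[1]]
        return out

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the given SNP column indices (order preserved)."""
        index = np.asarray(index)
        return GenotypePanel(
            dosages=self.dosages[:, index],
            snp_ids=self.snp_ids[index],
            chromosomes=self.chromosomes[index],
            positions=self.positions[index],
            individual_ids=self.individual_ids,
            allele_freq=self.allele_freq[index],
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        sub = GenotypePanel(
            dosages=self.dosages[index],
            snp_ids=self.snp_ids,
            chromosomes=self.chromosomes,
            positions=self.positions,
            individual_ids=self.individual_ids[index],
        )
        return sub

    def copy(self) -> "GenotypePanel":
        return replace(
            self,
            dosages=self.dosages.copy(),
            allele_freq=self.allele_freq.copy(),
        )
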