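"""Genomic relationship matrices: uniform (GCTA), LD-weighted (LDAK), stratified.

Dosages are standardized SNP-wise as x_ij = (m_ij − 2p_j)/sqrt(2p_j(1−p_j))
using the panel allele frequencies, which encodes the assumption that every
causal variant contributes equally to heritability. The uniform GRM is
G = XX'/N over the N panel SNPs; the LD-weighted GRM is G = XWX'/N with
W = diag(w*_j) holding scaled LD weights (Σ w* = N). Stratified GRMs build
one matrix per LD level from that level's SNPs alone, so that
Σ_t (N_t/N)·G_t = G for uniform weighting.

A reader/writer for the GCTA binary GRM triple (.grm.bin / .grm.N.bin /
.grm.id) is provided for interoperability with external REML software.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class GRMatrix:
    """Symmetric individuals × individuals genomic relationship matrix."""

    values: np.ndarray
    n_snps: int
    individual_ids: np.ndarray
    weighting: str = "uniform"  # or "ldak"
    label: str = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("GRM entries must be finite")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def standardize(panel: GenotypePanel, allele_freq: np.ndarray | None = None) -> np.ndarray:
    """Standardized dosage matrix X with x_ij = (m_ij − 2p_j)/sqrt(2p_j(1−p_j)).

    Allele frequencies default to those stored on the panel (computed on the
    full analysis sample); missing dosages are mean-imputed first, so an
    imputed entry standardizes to exactly 0.
    """
    p = panel.allele_freq if allele_freq is None else np.asarray(allele_freq, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)) or np.isnan(p).any():
        raise ValueError("standardization undefined for monomorphic SNPs (p in {0,1})")
    dos = panel.imputed_dosages()
    return (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def grm_gcta(x: np.ndarray, individual_ids: np.ndarray | None = None,
             label: str = "all") -> GRMatrix:
    """Uniform-weight GRM: G = XX'/N over the N columns of X."""
    x = np.asarray(x, dtype=float)
    n_snps = x.shape[1]
    if n_snps == 0:
        raise ValueError("cannot build a GRM from zero SNPs")
    if individual_ids is None:
        individual_ids = np.arange(x.shape[0])
    g = x @ x.T / n_snps
    g = (g + g.T) / 2.0
    return GRMatrix(g, n_snps, np.asarray(individual_ids, dtype=object),
                    weighting="uniform", label=label)


def grm_ldak(x: np.ndarray, weights_scaled: np.ndarray,
             individual_ids: np.ndarray | None = None, label: str = "all") -> GRMatrix:
    """LD-weighted GRM: G = X·diag(w*)·X'/N with scaled weights w* ≥ 0."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights_scaled, dtype=float)
    if len(w) != x.shape[1]:
        raise ValueError("weight vector length must equal SNP count")
    if np.any(w < 0):
        raise ValueError("LD weights must be non-negative")
    n_snps = x.shape[1]
    if n_snps == 0:
        raise ValueError("cannot build a GRM from zero SNPs")
    if individual_ids is None:
        individual_ids = np.arange(x.shape[0])
    g = (x * w) @ x.T / n_snps
    g = (g + g.T) / 2.0
    return GRMatrix(g, n_snps, np.asarray(individual_ids, dtype=object),
                    weighting="ldak", label=label)


def stratified_grms(
    panel: GenotypePanel,
    ld_levels: np.ndarray,
    weighting: str = "uniform",
    ldak_weights_raw: np.ndarray | None = None,
) -> list[GRMatrix]:
    """One GRM per LD level, built from that level's SNPs alone.

    ``ld_levels`` labels SNPs 1..T (must partition the panel). For LDAK
    weighting, raw weights are re-scaled *within each level* so Σ w* = N_t,
    keeping every component matrix on the same expected scale.
    """
    ld_levels = np.asarray(ld_levels)
    if len(ld_levels) != panel.n_snps:
        raise ValueError("ld_levels length mismatch")
    if weighting not in ("uniform", "ldak"):
        raise ValueError("weighting must be 'uniform' or 'ldak'")
    if weighting == "ldak" and ldak_weights_raw is None:
        raise ValueError("ldak weighting requires raw weights")
    x = standardize(panel)
    out = []
    for level in np.unique(ld_levels):
        idx = np.where(ld_levels == level)[0]
        if idx.size == 0:
            raise ValueError(f"empty LD level {level}")
        label = f"ld_level {level}"
        if weighting == "uniform":
            out.append(grm_gcta(x[:, idx], panel.individual_ids, label=label))
        else:
            w = np.asarray(ldak_weights_raw)[idx]
            w_star = w * (idx.size / w.sum())
            out.append(grm_ldak(x[:, idx], w_star, panel.individual_ids, label=label))
    return out


# ---------------------------------------------------------------------------
# GCTA binary GRM triple
# ---------------------------------------------------------------------------

def write_gcta_grm(grm: GRMatrix, prefix: str | Path) -> None:
    """Write .grm.bin (float32 lower triangle incl. diagonal, row-major),
    .grm.N.bin (float32 SNP count per pair) and .grm.id (FID IID text)."""
    prefix = Path(prefix)
    n = grm.n
    tril = grm.values[np.tril_indices(n)]
    tril.astype("<f4").tofile(Path(str(prefix) + ".grm.bin"))
    np.full(tril.shape, grm.n_snps, dtype="<f4").tofile(Path(str(prefix) + ".grm.N.bin"))
    pd.DataFrame({"fid": grm.individual_ids, "iid": grm.individual_ids}).to_csv(
        Path(str(prefix) + ".grm.id"), sep="\t", header=False, index=False
    )


def read_gcta_grm(prefix: str | Path) -> GRMatrix:
    """Read a GCTA binary GRM triple written by :func:`write_gcta_grm`."""
    prefix = Path(prefix)
    ids = pd.read_csv(Path(str(prefix) + ".grm.id"), sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    tril = np.fromfile(Path(str(prefix) + ".grm.bin"), dtype="<f4").astype(float)
    if tril.size != n * (n + 1) // 2:
        raise ValueError("GRM payload does not match id count")
    counts = np.fromfile(Path(str(prefix) + ".grm.N.bin"), dtype="<f4")
    g = np.zeros((n, n))
    g[np.tril_indices(n)] = tril
    g = g + np.tril(g, -1).T
    return GRMatrix(g, int(round(float(counts[0]))), ids["iid"].to_numpy(dtype=object))
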