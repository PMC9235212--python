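"""LD scores, regional mean LD scores, LD stratification, and LDAK weights.

All pairwise LD is the squared Pearson correlation r² of (mean-imputed)
genotype dosages. The per-SNP LD score sums r² with every SNP in a 10-Mb
window centered on the target SNP (self pair included, so every score ≥ 1);
windows never cross chromosome boundaries. Regional mean LD scores smooth
the per-SNP scores over ~100-kb sliding segments and drive the five-level LD
stratification used by the multi-component models. LDAK weights w_j solve a
per-chromosome non-negative least-squares system that drives each SNP's
*replicate tagging* Σ_k r²_jk·w_k toward 1, down-weighting SNPs in high-LD
regions and up-weighting SNPs in low-LD regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .panel import GenotypePanel


@dataclass
class LDProfile:
    """Per-SNP LD diagnostics for one panel."""

    ld_score: np.ndarray
    regional_score: np.ndarray
    ld_level: np.ndarray  # 1 (very high LD) .. n_groups (very low LD)
    ldak_weight: np.ndarray
    ldak_weight_scaled: np.ndarray
    replicate_tagging: np.ndarray


def _standardized(panel: GenotypePanel) -> np.ndarray:
    """Mean-centered, unit-variance dosage columns (empirical moments)."""
    dos = panel.imputed_dosages()
    x = dos - dos.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance SNP; run QC first")
    return x / sd


def pairwise_r2(panel: GenotypePanel, j: int, k: int) -> float:
    """Squared Pearson correlation between the dosage vectors of SNPs j and k."""
    dos = panel.imputed_dosages()[:, [j, k]]
    x = dos - dos.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance SNP; run QC first")
    r = float((x[:, 0] / sd[0]) @ (x[:, 1] / sd[1]) / x.shape[0])
    return r * r


def _chrom_r2(x: np.ndarray) -> np.ndarray:
    """Full r² matrix for standardized columns x (one chromosome)."""
    n = x.shape[0]
    r = (x.T @ x) / n
    return r * r


def snp_ld_score(panel: GenotypePanel, window_bp: int = 10_000_000) -> np.ndarray:
    """Σ_k r²_jk over SNPs k within ±window_bp/2 of SNP j, same chromosome.

    The self pair contributes 1, so scores are ≥ 1.
    """
    x = _standardized(panel)
    half = window_bp / 2.0
    scores = np.empty(panel.n_snps)
    for chrom in np.unique(panel.chromosomes):
        idx = np.where(panel.chromosomes == chrom)[0]
        pos = panel.positions[idx].astype(float)
        r2 = _chrom_r2(x[:, idx])
        in_win = np.abs(pos[:, None] - pos[None, :]) <= half
        scores[idx] = np.where(in_win, r2, 0.0).sum(axis=1)
    return scores


def regional_mean_ld_score(
    panel: GenotypePanel,
    ld_scores: np.ndarray,
    segment_bp: int = 100_000,
    step_bp: int = 50_000,
) -> np.ndarray:
    """Smooth per-SNP LD scores over sliding ~100-kb segments.

    Segments of length ``segment_bp`` advance by ``step_bp`` from the first
    SNP of each chromosome; a segment's value is the mean LD score of the
    SNPs inside it (closed interval), and each SNP's regional score is the
    mean over all segments containing it.
    """
    if segment_bp <= 0 or step_bp <= 0:
        raise ValueError("segment and step must be positive")
    ld_scores = np.asarray(ld_scores, dtype=float)
    regional = np.array(ld_scores, copy=True)  # fallback: own score
    for chrom in np.unique(panel.chromosomes):
        idx = np.where(panel.chromosomes == chrom)[0]
        pos = panel.positions[idx]
        lo, hi = int(pos.min()), int(pos.max())
        seg_sum = np.zeros(len(idx))
        seg_cnt = np.zeros(len(idx))
        start = lo
        while True:
            in_seg = (pos >= start) & (pos <= start + segment_bp - 1)
            if in_seg.any():
                seg_sum[in_seg] += ld_scores[idx][in_seg].mean()
                seg_cnt[in_seg] += 1
            if start + segment_bp - 1 >= hi:
                break
            start += step_bp
        covered = seg_cnt > 0
        regional[idx[covered]] = seg_sum[covered] / seg_cnt[covered]
    return regional


def ld_stratify(regional_scores: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Partition SNPs into LD levels 1 (very high) .. n_groups (very low).

    SNPs are sorted by regional score descending and cut into contiguous
    groups of equal size; any remainder is assigned from group 1 downward,
    so group sizes differ by at most one SNP.
    """
    scores = np.asarray(regional_scores, dtype=float)
    m = len(scores)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if m < n_groups:
        raise ValueError("fewer SNPs than groups")
    order = np.argsort(-scores, kind="stable")
    base, rem = divmod(m, n_groups)
    sizes = np.full(n_groups, base)
    sizes[:rem] += 1
    labels = np.empty(m, dtype=int)
    labels[order] = np.repeat(np.arange(1, n_groups + 1), sizes)
    return labels


def _nnls_ridge(a: np.ndarray, ridge: float) -> np.ndarray:
    """Non-negative least squares for A·w ≈ 1 with a small ridge penalty.

    The ridge makes the minimizer unique (and symmetric) when columns of A
    are identical, e.g. for perfectly correlated SNPs.
    """
    m = a.shape[0]
    a_aug = np.vstack([a, np.sqrt(ridge) * np.eye(m)])
    b_aug = np.concatenate([np.ones(m), np.zeros(m)])
    w, _resid = nnls(a_aug, b_aug)
    return w


def ldak_weights(
    panel: GenotypePanel,
    weight_window_bp: int = 1_000_000,
    ridge: float = 1e-4,
    chunk_size: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the LD-weighting system; return raw weights w and scaled w*.

    Per chromosome, minimize Σ_j (1 − Σ_{k∈win(j)} r²_jk · w_k)² over w ≥ 0,
    where win(j) is the ``weight_window_bp`` neighborhood of SNP j (window
    centered on j, self included). A tiny ridge penalty makes the minimizer
    unique when SNPs are perfectly correlated. Scaled weights satisfy
    Σ_j w*_j = N (the panel SNP count).

    Because r² outside the window does not enter the objective, the system
    is banded: long chromosomes are solved in chunks of ``chunk_size`` core
    SNPs with a full ``weight_window_bp`` buffer on each side, keeping only
    the core weights of each solve.
    """
    x = _standardized(panel)
    n_ind = panel.n_individuals
    half = weight_window_bp / 2.0
    w = np.empty(panel.n_snps)
    for chrom in np.unique(panel.chromosomes):
        idx = np.where(panel.chromosomes == chrom)[0]
        pos = panel.positions[idx].astype(float)
        m_c = len(idx)
        for start in range(0, m_c, chunk_size):
            core = np.arange(start, min(start + chunk_size, m_c))
            lo_bp = pos[core[0]] - weight_window_bp
            hi_bp = pos[core[-1]] + weight_window_bp
            ext = np.where((pos >= lo_bp) & (pos <= hi_bp))[0]
            r = (x[:, idx[ext]].T @ x[:, idx[ext]]) / n_ind
            r2 = r * r
            in_win = np.abs(pos[ext][:, None] - pos[ext][None, :]) <= half
            w_ext = _nnls_ridge(np.where(in_win, r2, 0.0), ridge)
            keep = np.searchsorted(ext, core)
            w[idx[core]] = w_ext[keep]
    w_scaled = w * (panel.n_snps / w.sum())
    return w, w_scaled


def replicate_tagging(
    panel: GenotypePanel,
    weights: np.ndarray | None = None,
    window_bp: int = 1_000_000,
) -> np.ndarray:
    """Per-SNP replicate tagging Σ_{k∈win(j)} r²_jk · weight_k (self included).

    With unit weights this measures how often a SNP's signal is duplicated by
    its neighbors in an unweighted GRM (≥ 1 always); after LD weighting it
    should sit near 1 for every SNP.
    """
    if weights is None:
        weights = np.ones(panel.n_snps)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != panel.n_snps:
        raise ValueError("weights length mismatch")
    x = _standardized(panel)
    half = window_bp / 2.0
    tagging = np.empty(panel.n_snps)
    for chrom in np.unique(panel.chromosomes):
        idx = np.where(panel.chromosomes == chrom)[0]
        pos = panel.positions[idx].astype(float)
        r = (x[:, idx].T @ x[:, idx]) / panel.n_individuals
        r2 = r * r
        mask = np.abs(pos[:, None] - pos[None, :]) <= half
        tagging[idx] = (np.where(mask, r2, 0.0) * weights[idx][None, :]).sum(axis=1)
    return tagging


def ld_profile(
    panel: GenotypePanel,
    score_window_bp: int = 10_000_000,
    segment_bp: int = 100_000,
    step_bp: int = 50_000,
    n_groups: int = 5,
    weight_window_bp: int = 1_000_000,
) -> LDProfile:
    """Convenience wrapper computing the full per-SNP LD profile."""
    scores = snp_ld_score(panel, score_window_bp)
    regional = regional_mean_ld_score(panel, scores, segment_bp, step_bp)
    levels = ld_stratify(regional, n_groups)
    w, w_star = ldak_weights(panel, weight_window_bp)
    tagging = replicate_tagging(panel, w, weight_window_bp)
    return LDProfile(
        ld_score=scores,
        regional_score=regional,
        ld_level=levels,
        ldak_weight=w,
        ldak_weight_scaled=w_star,
        replicate_tagging=tagging,
    )
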