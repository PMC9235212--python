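"""PLINK 1 binary genotype I/O, phenotype tables, and chip-style QC.

Implements the PLINK BED/BIM/FAM triple (SNP-major v1, magic bytes
``0x6c 0x1b 0x01``; two bits per genotype: ``00`` hom A1, ``01`` missing,
``10`` het, ``11`` hom A2) and standard quality-control filters: minor
allele frequency, per-SNP call rate, and a 1-df Pearson chi-square test of
Hardy–Weinberg equilibrium. Monomorphic SNPs are always removed because
genotype standardization is undefined at p ∈ {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK code -> A1 dosage (NaN = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised for malformed BED/BIM/FAM input."""


class EmptyPanelError(ValueError):
    """Raised when QC removes every SNP."""


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 BED/BIM/FAM triple into a :class:`GenotypePanel`.

    Dosages count the BIM A1 allele; individuals keep FAM order.
    """
    prefix = Path(prefix)
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp_id": str, "pos": np.int64},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam_df), len(bim_df)

    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes (not SNP-major PLINK v1)")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed}: payload {payload.size} B, expected {bytes_per_snp * m} B "
            f"for {n} individuals x {m} SNPs"
        )
    blocks = payload.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)

    return GenotypePanel(
        dosages=dosages,
        snp_ids=bim_df["snp_id"].to_numpy(),
        chromosomes=bim_df["chrom"].to_numpy(),
        positions=bim_df["pos"].to_numpy(),
        individual_ids=fam_df["iid"].to_numpy(),
    )


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write ``panel`` as a BED/BIM/FAM triple; ``read_plink`` round-trips it."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n_individuals, panel.n_snps

    dos = panel.dosages
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    codes[(dos == 2.0).T] = 0b00
    codes[(dos == 1.0).T] = 0b10
    codes[(dos == 0.0).T] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    blocks = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        blocks |= padded[:, k::4] << (2 * k)
    Path(str(prefix) + ".bed").write_bytes(_BED_MAGIC + blocks.tobytes())

    bim = pd.DataFrame({
        "chrom": panel.chromosomes,
        "snp_id": panel.snp_ids,
        "cm": 0,
        "pos": panel.positions,
        "a1": "A",
        "a2": "B",
    })
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": panel.individual_ids,
        "iid": panel.individual_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Phenotype / EBV tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited phenotype table.

    Columns: individual id, value, and optionally reliability r² ∈ (0, 1]
    (required for EBV deregression). Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] not in (2, 3):
        raise ValueError("phenotype table must have 2 or 3 columns (id, value[, reliability])")
    df.columns = ["individual_id", "value", "reliability"][: df.shape[1]]
    df["individual_id"] = df["individual_id"].astype(str)
    if df["individual_id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("individual_id", "value", "reliability") if c in df.columns]
    with open(path, "w") as fh:
        fh.write("# " + " ".join(cols) + "\n")
        df[cols].to_csv(fh, sep=" ", header=False, index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_fail_maf: int
    n_fail_callrate: int
    n_fail_hwe: int
    n_monomorphic: int


def hwe_chisq_pvalues(panel: GenotypePanel) -> np.ndarray:
    """1-df Pearson chi-square HWE p-value per SNP from genotype counts."""
    dos = panel.dosages
    n2 = np.nansum(dos == 2.0, axis=0).astype(float)  # hom A1
    n1 = np.nansum(dos == 1.0, axis=0).astype(float)
    n0 = np.nansum(dos == 0.0, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        q = 1.0 - p
        exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
        obs = np.stack([n0, n1, n2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs carry no HWE information
    pvals[(p <= 0) | (p >= 1) | np.isnan(p)] = 1.0
    return pvals


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    callrate_min: float = 0.9,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypePanel, QCReport]:
    """Apply MAF, call-rate and HWE filters; recompute allele frequencies.

    A SNP is removed if its MAF < ``maf_min``, its call rate < ``callrate_min``,
    or its HWE chi-square p-value < ``hwe_p_min``. Monomorphic SNPs are always
    removed. Returns the filtered panel and per-criterion removal counts.
    """
    if panel.n_snps == 0:
        raise EmptyPanelError("input panel has no SNPs")
    freq = panel.compute_allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    callrate = 1.0 - panel.missing_rate()
    hwe_p = hwe_chisq_pvalues(panel)

    mono = np.isnan(freq) | (freq <= 0.0) | (freq >= 1.0)
    fail_maf = (maf < maf_min) & ~mono if maf_min is not None else np.zeros_like(mono)
    fail_call = callrate < callrate_min
    fail_hwe = hwe_p < hwe_p_min
    keep = ~(mono | fail_maf | fail_call | fail_hwe)

    report = QCReport(
        n_input=panel.n_snps,
        n_retained=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_callrate=int(fail_call.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
        n_monomorphic=int(mono.sum()),
    )
    if report.n_retained == 0:
        raise EmptyPanelError("QC removed all SNPs")
    filtered = panel.subset_snps(np.where(keep)[0])
    filtered.allele_freq = filtered.compute_allele_freq()
    return filtered, report
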