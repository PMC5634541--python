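"""PLINK binary genotype I/O, cohort tables, and per-SNP/sample quality control.

Genotypes are held as additive counts of the bim A1 allele (PLINK
convention): the 2-bit bed codes 00/10/11/01 decode to dosages 2/1/0/missing.
Only SNP-major bed files (the modern default, third magic byte 0x01) are
supported; individual-major files are rejected.  Base-pair coordinates are
1-based inclusive throughout, as in bim files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1  # dosage code for a missing genotype

#: columns of the SNP metadata frame, mirroring a bim file
SNP_COLUMNS = ["chrom", "snp_id", "cm", "bp", "a1", "a2"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK code -> dosage of A1
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Malformed or unsupported PLINK binary input."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive allele-count matrix with metadata.

    dosage[i, j] counts copies of A1 for sample i at SNP j, in
    {0, 1, 2, MISSING}.
    """

    samples: list[str]
    snps: pd.DataFrame  # columns SNP_COLUMNS
    dosage: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triple given the shared path prefix."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None, names=SNP_COLUMNS,
        dtype={"chrom": int, "snp_id": str, "cm": float, "bp": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    samples = fam["iid"].tolist()
    n, m = len(samples), len(bim)

    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC[:2]:
        raise PlinkFormatError(f"{bed_path}: not a PLINK bed file (bad magic bytes)")
    if raw[2:3] != _BED_MAGIC[2:3]:
        raise PlinkFormatError(f"{bed_path}: individual-major bed files are not supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise PlinkFormatError(
            f"{bed_path}: {body.size} data bytes, expected {m * bytes_per_snp} "
            f"for {n} samples x {m} SNPs"
        )
    # unpack 2-bit codes, sample index runs through the low bits first
    mat = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)
    return GenotypeMatrix(samples, bim, np.ascontiguousarray(dosage))


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed (SNP-major), bim and fam files under the given prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g.snps[SNP_COLUMNS].to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": g.samples, "iid": g.samples, "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = g.n_samples, g.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    lut = np.zeros(4, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        lut[dos % 4] = code  # MISSING=-1 -> index 3
    codes[:, :n] = lut[g.dosage.T % 4]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of probabilities <= observed).

    The conditional distribution of the heterozygote count given the minor
    allele count is evaluated in closed form; the p-value sums the
    probabilities of all heterozygote counts no more likely than the one
    observed (no mid-p correction).
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homr = (n_minor - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1) - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QcThresholds:
    """SNP and sample filters: call rate, MAF, HWE and autosome restriction."""

    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    sample_call_rate_min: float = 0.95
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "maf_min", "hwe_p_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Counts of SNPs/samples removed, attributed to the first failing filter."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    snps_removed_autosome: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    samples_removed_call_rate: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, getattr(self, k)) for k in self.__dataclass_fields__],
            columns=["metric", "count"],
        )


def apply_qc(g: GenotypeMatrix, t: QcThresholds | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply SNP filters (autosome, call rate, MAF, HWE) then the sample
    call-rate filter, each in one pass.  HWE is tested on all samples."""
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    t = t or QcThresholds()
    rep = QcReport(n_snps_in=g.n_snps, n_samples_in=g.n_samples)

    obs = g.dosage != MISSING
    n_obs = obs.sum(axis=0)
    dos = np.where(obs, g.dosage, 0).astype(float)

    keep = np.ones(g.n_snps, dtype=bool)
    if t.autosomes_only:
        auto = g.snps["chrom"].to_numpy().astype(int)
        fail = ~((auto >= 1) & (auto <= 22))
        rep.snps_removed_autosome = int(fail[keep].sum())
        keep &= ~fail

    call = np.divide(n_obs, g.n_samples)
    fail = call < t.snp_call_rate_min
    rep.snps_removed_call_rate = int(fail[keep].sum())
    keep &= ~fail

    with np.errstate(invalid="ignore"):
        p_a1 = dos.sum(axis=0) / np.maximum(2 * n_obs, 1)
    maf = np.minimum(p_a1, 1 - p_a1)
    fail = ~(maf > t.maf_min)
    rep.snps_removed_maf = int(fail[keep].sum())
    keep &= ~fail

    n_het = ((g.dosage == 1) & obs).sum(axis=0)
    n_hom1 = (g.dosage == 2).sum(axis=0)
    n_hom2 = (g.dosage == 0).sum(axis=0)
    hwe_p = np.ones(g.n_snps)
    for j in np.nonzero(keep)[0]:
        hwe_p[j] = hwe_exact_p(int(n_het[j]), int(n_hom1[j]), int(n_hom2[j]))
    fail = ~(hwe_p > t.hwe_p_min)
    rep.snps_removed_hwe = int(fail[keep].sum())
    keep &= ~fail

    dosage = g.dosage[:, keep]
    snps = g.snps.loc[keep].reset_index(drop=True)

    if keep.sum() == 0:
        warnings.warn("QC removed every SNP; result is empty", stacklevel=2)
        sample_keep = np.ones(g.n_samples, dtype=bool)
    else:
        sample_call = (dosage != MISSING).mean(axis=1)
        sample_keep = sample_call >= t.sample_call_rate_min
    rep.samples_removed_call_rate = int((~sample_keep).sum())

    out = GenotypeMatrix(
        [s for s, k in zip(g.samples, sample_keep) if k], snps, dosage[sample_keep]
    )
    rep.n_snps_out = out.n_snps
    rep.n_samples_out = out.n_samples
    return out, rep


# ---------------------------------------------------------------------------
# Cohort tables

#: canonical cohort columns; sample_id plus a grade or presence column are mandatory
COHORT_COLUMNS = [
    "sample_id", "collaterals", "rentrop_grade", "age", "sex", "smoking",
    "diabetes", "dbp", "sbp", "vessel_disease", "left_main", "race_ethnicity",
]
_NUMERIC_COLS = ["collaterals", "rentrop_grade", "age", "sex", "smoking",
                 "diabetes", "dbp", "sbp", "left_main"]


@dataclass
class CohortTable:
    """Phenotype + covariate table for the cohort.

    ``collaterals`` is the presence/absence endpoint (1 = any Rentrop
    grade >= 1); ``rentrop_grade`` the ordinal 0-3 grade.  Sex is coded
    1 = male with female as reference.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if "sample_id" not in df.columns:
            raise ValueError("cohort table requires a sample_id column")
        if "rentrop_grade" not in df.columns and "collaterals" not in df.columns:
            raise ValueError("cohort table requires rentrop_grade or collaterals")
        grade = df.get("rentrop_grade")
        if grade is not None:
            bad = grade.dropna().loc[~grade.dropna().isin([0, 1, 2, 3])]
            if len(bad):
                raise ValueError(
                    f"rentrop_grade outside 0-3 at row(s) {bad.index.tolist()}: "
                    f"{bad.tolist()}"
                )
            if "collaterals" not in df.columns:
                df["collaterals"] = (grade >= 1).astype(float).where(grade.notna())
            else:
                both = grade.notna() & df["collaterals"].notna()
                if not (df.loc[both, "collaterals"] == (grade[both] >= 1)).all():
                    raise ValueError("collaterals inconsistent with rentrop_grade >= 1")
        for c in COHORT_COLUMNS:
            if c not in df.columns:
                df[c] = np.nan

    @property
    def n(self) -> int:
        return len(self.df)


def read_cohort(path: str | Path, schema: dict[str, str] | None = None) -> CohortTable:
    """Read a TSV/CSV phenotype/covariate file.

    ``schema`` maps canonical column names to file column names for files with
    non-standard headers.  Unparseable numeric cells become missing.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    schema = schema or {}
    df = pd.DataFrame()
    for canon in COHORT_COLUMNS:
        src = schema.get(canon, canon)
        if src in raw.columns:
            col = raw[src]
            if canon in _NUMERIC_COLS:
                col = pd.to_numeric(col, errors="coerce")
            df[canon] = col
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'sample_id'")
    return CohortTable(df)


def write_cohort_table(c: CohortTable, path: str | Path) -> None:
    c.df.to_csv(path, sep="\t", index=False)


def subset_genotypes(g: GenotypeMatrix, sample_ids: list[str]) -> GenotypeMatrix:
    """Restrict to the given samples, in the given order."""
    idx = {s: i for i, s in enumerate(g.samples)}
    missing = [s for s in sample_ids if s not in idx]
    if missing:
        raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
    rows = [idx[s] for s in sample_ids]
    return replace(g, samples=list(sample_ids), dosage=g.dosage[rows])
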