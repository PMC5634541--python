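"""Admixture-mapping scan: per-locus logistic models, permutation-based
multiple-testing correction, and peak-region extraction.

At every SNP the binary collateral phenotype is regressed on global African
and Native American ancestry, the global-minus-local differences at that
SNP, age and sex:

    logit P(Y=1) = b0 + b1*G_AFR + b2*G_NAM
                 + b3*(G_AFR - L_AFR) + b4*(G_NAM - L_NAM)
                 + b5*age + b6*sex

The delta (global minus local) terms are the mapped quantities: with global
ancestry controlled, a locus where local ancestry departs from an
individual's genome-wide average carries the admixture signal.  Genome-wide
significance comes from permuting the phenotype and taking the 5th
percentile of the minimum delta-term p-value: that percentile is the
corrected 0.05 threshold and 0.05 divided by it the effective number of
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._logistic import LogisticFit, fit_logistic
from .ancestry import GlobalAncestry, LocalAncestryField
from .io_formats import CohortTable

#: design-column order of the per-locus model
SCAN_TERMS = ["intercept", "g_afr", "g_nam", "delta_afr", "delta_nam", "age", "sex"]
DELTA_TERMS = ["delta_afr", "delta_nam"]


@dataclass
class ScanRow:
    """One locus: per-term coefficients and Wald p-values plus fit status."""

    snp_id: str
    chrom: int
    bp: int
    beta: dict[str, float]
    p: dict[str, float]
    se: dict[str, float]
    converged: bool


def fit_locus(
    y: np.ndarray,
    g_afr: np.ndarray,
    g_nam: np.ndarray,
    l_afr: np.ndarray,
    l_nam: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of the admixture model at one locus.

    Delta regressors are computed as global minus local.  Constant columns
    (e.g. delta identically zero when local equals global everywhere) get
    NaN coefficients while the rest equal the reduced-model fit; one-class
    outcomes or separation yield ``converged=False`` with NaN p-values.
    Coefficient order follows ``SCAN_TERMS``.
    """
    arrs = [np.asarray(a, dtype=float) for a in (g_afr, g_nam, l_afr, l_nam, age, sex)]
    g_afr, g_nam, l_afr, l_nam, age, sex = arrs
    X = np.column_stack(
        [np.ones_like(age), g_afr, g_nam, g_afr - l_afr, g_nam - l_nam, age, sex]
    )
    return fit_logistic(X, np.asarray(y, dtype=float))


def _aligned_inputs(
    local: LocalAncestryField, glob: GlobalAncestry, cohort: CohortTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    if local.sample_ids != glob.sample_ids:
        raise ValueError("local/global ancestry sample identifiers disagree")
    cdf = cohort.df.set_index("sample_id")
    missing = [s for s in local.sample_ids if s not in cdf.index]
    if missing:
        raise ValueError(f"cohort table lacks samples: {missing[:5]}")
    cdf = cdf.loc[local.sample_ids]

    y = cdf["collaterals"].to_numpy(float)
    age = cdf["age"].to_numpy(float)
    sex = cdf["sex"].to_numpy(float)
    keep = ~(np.isnan(y) | np.isnan(age) | np.isnan(sex))
    n_dropped = int((~keep).sum())

    labels = list(local.ancestry_labels)
    i_afr, i_nam = labels.index("AFR"), labels.index("NAM")
    lv = local.values[keep][:, :, [i_afr, i_nam]]
    gv = glob.values[keep][:, [i_afr, i_nam]]
    return y[keep], gv[:, 0], gv[:, 1], lv, age[keep], sex[keep], n_dropped


def admixture_scan(
    local: LocalAncestryField,
    glob: GlobalAncestry,
    cohort: CohortTable,
    verbose: bool = False,
) -> pd.DataFrame:
    """Fit the per-locus admixture model at every SNP.

    Inputs are aligned by sample identifier (hard error on mismatch); samples
    with a missing phenotype, age or sex are dropped once before the scan
    (complete-case).  Returns a tidy frame with per-term ``beta_*`` and
    ``p_*`` columns and a convergence flag, sorted by (chrom, bp).
    """
    y, g_afr, g_nam, lv, age, sex, n_dropped = _aligned_inputs(local, glob, cohort)
    if verbose and n_dropped:
        warnings.warn(f"admixture_scan: dropped {n_dropped} incomplete samples",
                      stacklevel=2)
    rows = []
    snps = local.snps
    for j in range(lv.shape[1]):
        fit = fit_locus(y, g_afr, g_nam, lv[:, j, 0], lv[:, j, 1], age, sex)
        rec = {
            "chrom": snps["chrom"].iat[j], "bp": snps["bp"].iat[j],
            "snp_id": snps["snp_id"].iat[j], "converged": fit.converged,
        }
        for t, term in enumerate(SCAN_TERMS):
            rec[f"beta_{term}"] = fit.beta[t]
            rec[f"se_{term}"] = fit.se[t]
            rec[f"p_{term}"] = fit.p[t]
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values(["chrom", "bp"], kind="mergesort")
    out.attrs["n_samples_used"] = int(len(y))
    out.attrs["n_samples_dropped"] = n_dropped
    return out.reset_index(drop=True)


@dataclass
class PermutationSummary:
    """Permutation null distribution of the genome-wide minimum delta-term
    p-value.  ``p5`` (nearest-rank, lower) is the multiple-testing-corrected
    0.05 threshold; 0.05/p5 (floored) the effective number of tests."""

    n_permutations: int
    min_p_per_permutation: list[float]
    p5: float
    effective_tests: int
    effective_tests_ratio: float
    corrected_threshold: float
    seed: int
    mode: str = "joint"

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "p5": self.p5,
            "effective_tests": self.effective_tests,
            "effective_tests_ratio": self.effective_tests_ratio,
            "corrected_threshold": self.corrected_threshold,
            "seed": self.seed,
            "mode": self.mode,
            "min_p_per_permutation": self.min_p_per_permutation,
        }


def nearest_rank_lower(values: np.ndarray, q: float) -> float:
    """Empirical q-quantile by the nearest-rank (lower) definition:
    the k-th smallest value with k = max(1, floor(q*n))."""
    v = np.sort(np.asarray(values, dtype=float))
    k = max(1, int(np.floor(q * len(v))))
    return float(v[k - 1])


def effective_tests(p5: float) -> tuple[int, float]:
    """Effective number of independent tests: 0.05/p5 floored to an integer
    (unrounded ratio returned alongside).  A p5 above 0.05 means fewer than
    one effective test; returns 1 with a warning."""
    if not 0.0 < p5:
        raise ValueError("p5 must be positive")
    if p5 > 0.05:
        warnings.warn(f"p5={p5} exceeds 0.05; reporting a single effective test",
                      stacklevel=2)
        return 1, 0.05 / p5
    ratio = 0.05 / p5
    return int(np.floor(ratio)), ratio


def threshold_for_tests(n_tests: int) -> float:
    """Corrected per-test threshold implied by n effective tests: 0.05/n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / n_tests


def min_delta_p(scan_df: pd.DataFrame, mode: str = "joint") -> float:
    """Genome-wide minimum p over the delta terms.  Non-converged or NaN
    entries count as p=1 (conservative).  Mode: 'joint' (both ancestries),
    'afr' or 'nam'."""
    cols = {"joint": ["p_delta_afr", "p_delta_nam"], "afr": ["p_delta_afr"],
            "nam": ["p_delta_nam"]}[mode]
    p = scan_df.loc[scan_df["converged"], cols].to_numpy(float)
    p = np.where(np.isnan(p), 1.0, p)
    return float(p.min()) if p.size else 1.0


def permutation_threshold(
    local: LocalAncestryField,
    glob: GlobalAncestry,
    cohort: CohortTable,
    B: int = 2000,
    seed: int = 0,
    mode: str = "joint",
) -> PermutationSummary:
    """Permutation-based genome-wide correction.

    The phenotype vector is shuffled B times across samples (covariates and
    ancestry stay attached to their samples); each permutation re-runs the
    scan and records the genome-wide minimum delta-term p-value.  The 5th
    percentile of those minima is the corrected 0.05 threshold.
    """
    if B < 20:
        raise ValueError("B must be >= 20 for a 5th percentile to exist")
    y, g_afr, g_nam, lv, age, sex, _ = _aligned_inputs(local, glob, cohort)
    rng = np.random.default_rng(seed)
    m = lv.shape[1]
    term_idx = {"joint": [3, 4], "afr": [3], "nam": [4]}[mode]

    mins = np.empty(B)
    for b in range(B):
        yp = rng.permutation(y)
        best = 1.0
        for j in range(m):
            fit = fit_locus(yp, g_afr, g_nam, lv[:, j, 0], lv[:, j, 1], age, sex)
            if fit.converged:
                pj = np.nanmin(np.append(fit.p[term_idx], 1.0))
                if pj < best:
                    best = float(pj)
        mins[b] = best
    p5 = nearest_rank_lower(mins, 0.05)
    eff, ratio = effective_tests(p5)
    return PermutationSummary(B, mins.tolist(), p5, eff, ratio, p5, seed, mode)


@dataclass
class PeakRegion:
    """Maximal run of consecutive scan SNPs whose term p-value is at or below
    the cut; bounds are the bp of the first and last qualifying SNP
    (1-based inclusive)."""

    chrom: int
    start_bp: int
    end_bp: int
    term: str
    min_p: float
    beta_at_min: float
    n_snps: int = 0


def peak_regions(scan_df: pd.DataFrame, term: str, p_cut: float) -> list[PeakRegion]:
    """Extract significant regions for one ancestry term from a scan sorted
    by (chrom, bp): consecutive qualifying SNPs merge into one region."""
    pcol, bcol = f"p_{term}", f"beta_{term}"
    if pcol not in scan_df.columns:
        raise KeyError(f"scan has no term '{term}'")
    df = scan_df.reset_index(drop=True)
    hit = df[pcol].to_numpy(float) <= p_cut
    hit &= ~np.isnan(df[pcol].to_numpy(float))
    regions: list[PeakRegion] = []
    i = 0
    n = len(df)
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hit[j + 1] and df["chrom"].iat[j + 1] == df["chrom"].iat[i]:
            j += 1
        block = df.iloc[i: j + 1]
        kmin = block[pcol].idxmin()
        regions.append(
            PeakRegion(
                chrom=int(df["chrom"].iat[i]),
                start_bp=int(df["bp"].iat[i]),
                end_bp=int(df["bp"].iat[j]),
                term=term,
                min_p=float(block[pcol].min()),
                beta_at_min=float(df.loc[kmin, bcol]),
                n_snps=j - i + 1,
            )
        )
        i = j + 1
    return regions
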