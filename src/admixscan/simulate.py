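"""Synthetic three-way admixed cohorts with known local-ancestry truth.

The generator produces everything the downstream pipeline consumes: phased
haplotypes with per-SNP ancestry labels, unphased genotypes, a binary
collateral phenotype generated from the same logistic model the scan fits,
an ordinal Rentrop grade from a proportional-odds model, and clinical
covariates.  Ancestral allele frequencies follow the Balding-Nichols model;
chromosomes are mosaics of ancestry tracts from a Poisson breakpoint process
(rate = admixture age in generations, per Morgan), with tract ancestries
drawn i.i.d. from each individual's Dirichlet admixture proportions.

Ancestry index convention throughout the package: 0 = European-like (EUR),
1 = African-like (AFR), 2 = Native-American-like (NAM).  The mapped
quantities are the AFR and NAM components (G_AFR, G_NAM and their
global-minus-local differences).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_formats import GenotypeMatrix, CohortTable, write_plink, write_cohort_table

ANCESTRY_LABELS = ("EUR", "AFR", "NAM")
EUR, AFR, NAM = 0, 1, 2

#: physical map scale: 1 centiMorgan = 1 Mb
BP_PER_CM = 1_000_000


@dataclass
class PhenoCoefs:
    """Coefficients of the generative binary-collateral logistic model
    (intercept, global AFR/NAM ancestry, global-minus-local differences at
    the causal locus, age in years, sex with 1 = male)."""

    intercept: float = 0.12
    b_g_afr: float = 0.0
    b_g_nam: float = 0.0
    b_delta_afr: float = 0.0
    b_delta_nam: float = 0.0
    b_age: float = -0.01
    b_sex: float = 0.6


@dataclass
class OrdinalCoefs:
    """Proportional-odds model for the Rentrop grade: sex/smoking/diabetes
    effects, race-ethnicity treatment contrasts vs the Hispanic reference,
    and three increasing cutpoints on the cumulative-logit scale.

    Default cutpoints are logit of the cumulative grade frequencies
    (0.47, 0.63, 0.87) shifted by the mean linear predictor (~0.6) so the
    marginal grade distribution stays near 47/16/24/13%.
    """

    b_sex: float = 0.59
    b_smoking: float = 0.38
    b_diabetes: float = 0.2
    b_cauc: float = -0.39
    b_aa: float = -0.23
    cutpoints: tuple[float, float, float] = (0.48, 1.13, 2.50)

    def __post_init__(self) -> None:
        if not (self.cutpoints[0] < self.cutpoints[1] < self.cutpoints[2]):
            raise ValueError("cutpoints must be strictly increasing")


@dataclass
class SimConfig:
    """Study-scale defaults: 600 individuals, three 1-Morgan chromosomes of
    1000 SNPs each, K=3 ancestries at Fst 0.15, admixture age 8 generations,
    Dirichlet(6, 2.5, 1.5) admixture (European-major, Hispanic-like)."""

    n_individuals: int = 600
    n_snps: int = 3000
    n_chromosomes: int = 3
    chrom_length_morgans: float = 1.0
    k_ancestries: int = 3
    fst: tuple[float, ...] = (0.15, 0.15, 0.15)
    admixture_alpha: tuple[float, ...] = (6.0, 2.5, 1.5)
    generations: float = 8.0
    pheno_coefs: PhenoCoefs = field(default_factory=PhenoCoefs)
    causal_locus: int | None = None
    target_prevalence: float | None = 0.53
    ordinal_coefs: OrdinalCoefs = field(default_factory=OrdinalCoefs)
    seed: int = 2024

    def __post_init__(self) -> None:
        if len(self.fst) != self.k_ancestries or len(self.admixture_alpha) != self.k_ancestries:
            raise ValueError("fst and admixture_alpha must have k_ancestries entries")
        if not all(0.0 < f < 1.0 for f in self.fst):
            raise ValueError("fst values must lie in (0, 1)")
        if self.causal_locus is not None and not 0 <= self.causal_locus < self.n_snps:
            raise ValueError("causal_locus outside SNP range")


@dataclass
class TrueAncestry:
    """Ground-truth ancestry: per-haplotype per-SNP labels plus the tract
    intervals (1-based inclusive bp) they derive from."""

    labels: np.ndarray  # uint8, shape (n, 2, m)
    tracts: pd.DataFrame  # individual, hap, chrom, start_bp, end_bp, ancestry
    k: int

    def local_proportions(self) -> np.ndarray:
        """Diploid local-ancestry proportions (n, m, k) in {0, 0.5, 1}."""
        n, _, m = self.labels.shape
        out = np.zeros((n, m, self.k))
        for a in range(self.k):
            out[:, :, a] = (self.labels == a).mean(axis=1)
        return out

    def global_proportions(self) -> np.ndarray:
        """Genome-average ancestry proportions (n, k); SNP-grid average."""
        return self.local_proportions().mean(axis=1)


def snp_map(cfg: SimConfig) -> pd.DataFrame:
    """SNP metadata frame: chromosomes 1..C, evenly spaced genetic positions,
    physical positions at 1 cM = 1 Mb."""
    per = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    j = 0
    for c in range(cfg.n_chromosomes):
        mc = per[c]
        pos_m = (np.arange(mc) + 0.5) * cfg.chrom_length_morgans / mc
        for pm in pos_m:
            cm = 100.0 * pm
            rows.append((c + 1, f"snp{j}", cm, int(round(cm * BP_PER_CM)) + 1, "A", "G"))
            j += 1
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "bp", "a1", "a2"])


def balding_nichols_freqs(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Population allele frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral frequency p (one draw per entry of p)."""
    p = np.asarray(p, dtype=float)
    r = (1.0 - fst) / fst
    return rng.beta(p * r, (1.0 - p) * r)


def draw_ancestral_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(k, m) allele-frequency panel: ancestral p ~ U(0.05, 0.95) per SNP,
    each population a Balding-Nichols draw at its Fst, clipped away from
    fixation by 1e-4."""
    p = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    freqs = np.vstack([balding_nichols_freqs(p, f, rng) for f in cfg.fst])
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def draw_admixture_proportions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(cfg.admixture_alpha, size=cfg.n_individuals)


def sim_admixed_haplotypes(
    cfg: SimConfig,
    freqs: np.ndarray,
    rng: np.random.Generator,
    props: np.ndarray | None = None,
    draw_alleles: bool = True,
) -> tuple[np.ndarray | None, TrueAncestry, np.ndarray]:
    """Simulate phased haplotypes as ancestry-tract mosaics.

    Breakpoints fall at Poisson rate ``generations`` per Morgan; each tract's
    ancestry is an i.i.d. draw from the individual's admixture proportions;
    alleles are Bernoulli draws from the tract ancestry's panel frequency.
    Chromosomes are independent.  With ``draw_alleles=False`` only the
    ancestry truth is generated (cheap path for phenotype-model studies).

    Returns (haplotypes (n, 2, m) int8 or None, TrueAncestry, proportions).
    """
    snps = snp_map(cfg)
    if props is None:
        props = draw_admixture_proportions(cfg, rng)
    n, m, k = cfg.n_individuals, cfg.n_snps, cfg.k_ancestries
    labels = np.empty((n, 2, m), dtype=np.uint8)
    tract_rows: list[tuple] = []
    L = cfg.chrom_length_morgans

    chrom_arr = snps["chrom"].to_numpy()
    pos_m = snps["cm"].to_numpy() / 100.0
    bp = snps["bp"].to_numpy()
    for c in range(1, cfg.n_chromosomes + 1):
        sl = np.nonzero(chrom_arr == c)[0]
        pos_c, bp_c = pos_m[sl], bp[sl]
        chrom_end_bp = int(round(L * 100 * BP_PER_CM))
        for i in range(n):
            for h in range(2):
                nb = rng.poisson(cfg.generations * L)
                cuts = np.sort(rng.uniform(0.0, L, size=nb))
                anc = rng.choice(k, size=nb + 1, p=props[i])
                seg = np.searchsorted(cuts, pos_c, side="right")
                labels[i, h, sl] = anc[seg].astype(np.uint8)
                bounds = np.concatenate([[0.0], cuts, [L]])
                for s in range(nb + 1):
                    start = int(round(bounds[s] * 100 * BP_PER_CM)) + 1
                    end = int(round(bounds[s + 1] * 100 * BP_PER_CM))
                    end = min(end, chrom_end_bp)
                    if end >= start:
                        tract_rows.append((i, h, c, start, end, int(anc[s])))

    tracts = pd.DataFrame(
        tract_rows, columns=["individual", "hap", "chrom", "start_bp", "end_bp", "ancestry"]
    )
    truth = TrueAncestry(labels, tracts, k)
    haps = None
    if draw_alleles:
        site_f = freqs[labels, np.arange(m)[None, None, :]]
        haps = (rng.random((n, 2, m)) < site_f).astype(np.int8)
    return haps, truth, props


def calibrate_intercept(lp_no_intercept: np.ndarray, target: float) -> float:
    """Intercept making mean expit(intercept + lp) equal the target prevalence."""
    f = lambda b0: float(np.mean(expit(b0 + lp_no_intercept))) - target
    return brentq(f, -30.0, 30.0)


def binary_linear_predictor(
    coefs: PhenoCoefs,
    g_afr: np.ndarray,
    g_nam: np.ndarray,
    l_afr: np.ndarray | None,
    l_nam: np.ndarray | None,
    age: np.ndarray,
    sex: np.ndarray,
    include_intercept: bool = True,
) -> np.ndarray:
    lp = (
        coefs.b_g_afr * g_afr
        + coefs.b_g_nam * g_nam
        + coefs.b_age * age
        + coefs.b_sex * sex
    )
    if l_afr is not None:
        lp = lp + coefs.b_delta_afr * (g_afr - l_afr)
    if l_nam is not None:
        lp = lp + coefs.b_delta_nam * (g_nam - l_nam)
    if include_intercept:
        lp = lp + coefs.intercept
    return lp


def sim_binary_phenotype(
    truth: TrueAncestry,
    cfg: SimConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary collateral phenotype from the admixture logistic model.

    Delta (global minus local) terms are evaluated at ``cfg.causal_locus``
    from TRUE ancestry; with no causal locus the delta coefficients are
    unused and the model is null with respect to local ancestry.  When
    ``cfg.target_prevalence`` is set the intercept is calibrated so the
    marginal expected prevalence matches it.
    """
    glob = truth.global_proportions()
    l_afr = l_nam = None
    if cfg.causal_locus is not None:
        loc = truth.local_proportions()[:, cfg.causal_locus, :]
        l_afr, l_nam = loc[:, AFR], loc[:, NAM]
    lp = binary_linear_predictor(
        cfg.pheno_coefs, glob[:, AFR], glob[:, NAM], l_afr, l_nam,
        covariates["age"].to_numpy(float), covariates["sex"].to_numpy(float),
        include_intercept=False,
    )
    b0 = cfg.pheno_coefs.intercept
    if cfg.target_prevalence is not None:
        b0 = calibrate_intercept(lp, cfg.target_prevalence)
    return (rng.random(len(lp)) < expit(b0 + lp)).astype(np.int8)


def _ordinal_cumulative(cov: pd.DataFrame, coefs: OrdinalCoefs) -> np.ndarray:
    race = cov["race_ethnicity"].astype(str)
    lp = (
        coefs.b_sex * cov["sex"].to_numpy(float)
        + coefs.b_smoking * cov["smoking"].to_numpy(float)
        + coefs.b_diabetes * cov["diabetes"].to_numpy(float)
        + coefs.b_cauc * (race == "CAUC").to_numpy(float)
        + coefs.b_aa * (race == "AA").to_numpy(float)
    )
    cuts = np.asarray(coefs.cutpoints)
    return expit(cuts[None, :] - lp[:, None])  # (n, 3): P(grade <= k)


def sim_ordinal_grades(
    covariates: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    condition_on: np.ndarray | None = None,
) -> np.ndarray:
    """Rentrop grades 0-3 from the proportional-odds model
    P(grade <= k) = expit(cutpoint_k - x'beta).

    ``condition_on`` (a binary presence vector) forces grade 0 where it is 0
    and draws from the conditional distribution over grades 1-3 where it is 1,
    preserving the collaterals = (grade >= 1) identity in full-cohort runs.
    """
    cum = _ordinal_cumulative(covariates, cfg.ordinal_coefs)
    u = rng.random(len(cum))
    if condition_on is None:
        return (u[:, None] > cum).sum(axis=1).astype(np.int8)
    y = np.asarray(condition_on).astype(int)
    grades = np.zeros(len(cum), dtype=np.int8)
    pos = y == 1
    if pos.any():
        p0 = cum[pos, 0]
        denom = np.maximum(1.0 - p0, 1e-12)
        # conditional cumulative over grades 1..3 given grade >= 1
        cond = (cum[pos, 1:] - p0[:, None]) / denom[:, None]
        grades[pos] = 1 + (u[pos, None] > cond).sum(axis=1)
    return grades


def sim_covariates(
    cfg: SimConfig, props: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical covariates with the cohort's approximate marginals: age
    ~N(71, 12), 74% male, 56% smokers, 45% diabetic, DBP ~N(76, 13),
    SBP ~N(140, 24), vessel-disease classes 37/29/34% with ~2.4% missing.
    Race-ethnicity labels derive from admixture proportions."""
    n = cfg.n_individuals
    race = np.where(
        props[:, AFR] >= 0.5, "AA",
        np.where(props[:, NAM] + props[:, AFR] >= 0.10, "HISP",
                 np.where(props[:, EUR] >= 0.90, "CAUC", "unclassified")),
    )
    vd = rng.choice(["1VD", "2VD", "3VD"], size=n, p=[0.37, 0.29, 0.34]).astype(object)
    vd[rng.random(n) < 0.024] = np.nan
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(71, 12, n), 30, 95).round(1),
            "sex": (rng.random(n) < 0.74).astype(int),
            "smoking": (rng.random(n) < 0.56).astype(int),
            "diabetes": (rng.random(n) < 0.45).astype(int),
            "dbp": np.clip(rng.normal(76, 13, n), 40, 130).round(0),
            "sbp": np.clip(rng.normal(140, 24, n), 80, 230).round(0),
            "vessel_disease": vd,
            "left_main": (rng.random(n) < 0.12).astype(int),
            "race_ethnicity": race,
        }
    )


@dataclass
class SimulatedCohort:
    """Bundle of every artifact one simulation run produces."""

    cfg: SimConfig
    snps: pd.DataFrame
    freqs: np.ndarray  # (k, m) ancestral-panel frequencies
    haplotypes: np.ndarray  # (n, 2, m) 0/1
    truth: TrueAncestry
    admixture: np.ndarray  # (n, k) drawn proportions
    genotypes: GenotypeMatrix  # unphased hap sums, A1 = counted allele
    cohort: CohortTable

    @property
    def sample_ids(self) -> list[str]:
        return self.genotypes.samples


def simulate_cohort(cfg: SimConfig | None = None, rng: np.random.Generator | None = None) -> SimulatedCohort:
    """End-to-end cohort simulation: panels, haplotypes, covariates,
    binary phenotype from the admixture model, conditional Rentrop grades."""
    cfg = cfg or SimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    freqs = draw_ancestral_freqs(cfg, rng)
    haps, truth, props = sim_admixed_haplotypes(cfg, freqs, rng)
    cov = sim_covariates(cfg, props, rng)
    y = sim_binary_phenotype(truth, cfg, cov, rng)
    grades = sim_ordinal_grades(cov, cfg, rng, condition_on=y)

    samples = [f"ind{i}" for i in range(cfg.n_individuals)]
    # bim A1 is the simulated '1' allele, so dosage = haplotype sum
    geno = GenotypeMatrix(samples, snp_map(cfg), haps.sum(axis=1).astype(np.int8))
    df = pd.DataFrame({"sample_id": samples, "collaterals": y.astype(float),
                       "rentrop_grade": grades.astype(float)})
    cohort = CohortTable(pd.concat([df, cov], axis=1))
    return SimulatedCohort(cfg, snp_map(cfg), freqs, haps, truth, props, geno, cohort)


def write_cohort(sim: SimulatedCohort, outdir: str | Path) -> dict[str, str]:
    """Write PLINK files, phased haplotypes, ancestry truth, panels, cohort
    table and a manifest (config + seed) under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_plink(sim.genotypes, out / "cohort")

    n, _, m = sim.haplotypes.shape
    hap_mat = sim.haplotypes.reshape(2 * n, m)
    hap_ids = [f"{s}.h{h}" for s in sim.sample_ids for h in (0, 1)]
    pd.DataFrame(hap_mat, index=hap_ids).to_csv(out / "haplotypes.tsv", sep="\t", header=False)

    tr = sim.truth.tracts.copy()
    tr["sample_id"] = [sim.sample_ids[i] for i in tr["individual"]]
    tr["ancestry"] = [ANCESTRY_LABELS[a] for a in tr["ancestry"]]
    tr[["chrom", "start_bp", "end_bp", "sample_id", "hap", "ancestry"]].to_csv(
        out / "true_tracts.tsv", sep="\t", index=False
    )

    panel = sim.snps[["chrom", "snp_id", "cm", "bp"]].copy()
    for a, lab in enumerate(ANCESTRY_LABELS[: sim.cfg.k_ancestries]):
        panel[f"freq_{lab}"] = sim.freqs[a]
    panel.to_csv(out / "panel_freqs.tsv", sep="\t", index=False)

    write_cohort_table(sim.cohort, out / "cohort.tsv")
    manifest = {"config": dataclasses.asdict(sim.cfg), "seed": sim.cfg.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "plink": str(out / "cohort"),
        "haplotypes": str(out / "haplotypes.tsv"),
        "true_tracts": str(out / "true_tracts.tsv"),
        "panel_freqs": str(out / "panel_freqs.tsv"),
        "cohort": str(out / "cohort.tsv"),
        "manifest": str(out / "manifest.json"),
    }
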