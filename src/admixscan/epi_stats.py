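"""Epidemiological statistics for the collateralization cohort.

Contingency-table chi-square tests (collateral grade vs vessel-disease
severity or race-ethnicity), one-way ANOVA on continuous traits,
proportional-odds ordinal regression of the Rentrop grade, presence/absence
logistic regression of individual SNPs with principal-component covariates,
univariate covariate screening, and the regional permutation estimate of the
number of independent SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import fit_logistic
from .scan import effective_tests, nearest_rank_lower

#: reference level for race-ethnicity treatment contrasts
RACE_REFERENCE = "HISP"


def contingency_chisq(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (chi2, df, p) with df = (r-1)(c-1).  A zero row or column margin
    is an error naming the offending margin.
    """
    df_in = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    counts = df_in.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    rs, cs = counts.sum(axis=1), counts.sum(axis=0)
    for margin, sums, labels in (("row", rs, df_in.index), ("column", cs, df_in.columns)):
        if np.any(sums == 0):
            bad = [str(labels[i]) for i in np.nonzero(sums == 0)[0]]
            raise ValueError(f"zero {margin} margin: {bad}")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(dof), float(p)


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA across groups: (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(f), df1, df2, float(p)


@dataclass
class OrdinalFit:
    """Proportional-odds fit: per-covariate slopes with Wald inference,
    strictly increasing cutpoints, log-likelihood, convergence flag."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    cutpoints: np.ndarray
    loglik: float
    converged: bool
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "estimate": self.beta, "std_error": self.se,
             "p": self.p}
        )


def _expand_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Treatment-contrast expansion of string-valued columns.  For
    race_ethnicity the reference is Hispanic, giving CAUC-vs-HISP and
    AA-vs-HISP contrasts."""
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            s = s.astype(str)
            levels = [v for v in pd.unique(s) if v not in ("nan", "None")]
            ref = RACE_REFERENCE if RACE_REFERENCE in levels else sorted(levels)[0]
            for lev in sorted(v for v in levels if v != ref):
                out[f"{col}[{lev}]"] = (s == lev).astype(float)
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=covariates.index)


def ordinal_logit(grade: np.ndarray | pd.Series, covariates: pd.DataFrame) -> OrdinalFit:
    """Cumulative-logit (proportional-odds) ML fit of an ordered grade on
    the given covariates: P(grade <= k) = expit(cutpoint_k - x'beta), so a
    positive slope shifts mass toward higher grades.

    String covariates enter as treatment contrasts (Hispanic reference for
    race-ethnicity); incomplete rows are dropped.  Separation or optimizer
    failure is flagged, not raised.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    X = _expand_design(covariates)
    g = pd.Series(np.asarray(grade, dtype=float), index=X.index)
    keep = g.notna() & X.notna().all(axis=1)
    g, X = g[keep], X.loc[keep]
    if g.nunique() < 2:
        raise ValueError("grade must have at least two observed levels")
    terms = list(X.columns)
    k_levels = int(g.nunique())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(g.to_numpy(), X.to_numpy(), distr="logit")
            res = model.fit(method="bfgs", maxiter=1000, gtol=1e-10, disp=False)
            if not res.mle_retvals.get("converged", True):
                # BFGS with numerical gradients bottoms out on large samples;
                # a simplex polish from its solution settles the flag
                res = model.fit(start_params=res.params, method="nm",
                                maxiter=5000, xtol=1e-10, ftol=1e-12, disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
        nk = len(terms)
        beta = np.asarray(res.params[:nk], dtype=float)
        se = np.asarray(res.bse[:nk], dtype=float)
        p = np.asarray(res.pvalues[:nk], dtype=float)
        cuts = model.transform_threshold_params(res.params)[1:-1]
        ll = float(res.llf)
    except Exception:  # separation / singular information
        nk = len(terms)
        beta = se = p = np.full(nk, np.nan)
        cuts = np.full(k_levels - 1, np.nan)
        ll, converged = np.nan, False
    if converged and not np.all(np.isfinite(se)):
        converged = False
        p = np.full(len(terms), np.nan)
    return OrdinalFit(terms, beta, se, p, np.asarray(cuts, float), ll, converged,
                      int(keep.sum()))


@dataclass
class SnpAssocRow:
    """Regional SNP association: additive-genotype effect with covariates."""

    snp_id: str
    beta_genotype: float
    se_genotype: float
    p_genotype: float
    covariate_beta: dict[str, float]
    converged: bool
    n_obs: int
    reason: str = ""


def binary_logit_snp(
    y: np.ndarray,
    genotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "",
) -> SnpAssocRow:
    """Logistic regression of presence/absence collaterals on an additive
    0/1/2 genotype dosage plus covariates (eigenvectors, age, sex in the
    regional model).  Complete-case; a constant genotype yields an NA row
    with a reason code instead of an error."""
    y = np.asarray(y, dtype=float)
    geno = np.asarray(genotype, dtype=float)
    cov = covariates if covariates is not None else pd.DataFrame(index=range(len(y)))
    C = cov.to_numpy(dtype=float) if len(cov.columns) else np.empty((len(y), 0))
    keep = ~(np.isnan(y) | np.isnan(geno) | np.isnan(C).any(axis=1))
    y, geno, C = y[keep], geno[keep], C[keep]
    names = list(cov.columns)
    if np.all(geno == geno[0] if geno.size else True):
        return SnpAssocRow(snp_id, np.nan, np.nan, np.nan,
                           {c: np.nan for c in names}, False, int(keep.sum()),
                           reason="constant_genotype")
    X = np.column_stack([np.ones_like(y), geno, C])
    fit = fit_logistic(X, y)
    return SnpAssocRow(
        snp_id,
        float(fit.beta[1]), float(fit.se[1]), float(fit.p[1]),
        {c: float(fit.beta[2 + i]) for i, c in enumerate(names)},
        fit.converged, int(keep.sum()),
        reason="" if fit.converged else "non_convergence",
    )


def covariate_screen(
    candidates: pd.DataFrame, y: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Univariate logistic screen: keep candidates whose Wald p < alpha,
    in input column order."""
    y = np.asarray(y, dtype=float)
    selected = []
    for col in candidates.columns:
        x = candidates[col].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        fit = fit_logistic(np.column_stack([np.ones(keep.sum()), x[keep]]), y[keep])
        if fit.converged and np.isfinite(fit.p[1]) and fit.p[1] < alpha:
            selected.append(col)
    return selected


def region_effective_snps(
    y: np.ndarray,
    genotypes: np.ndarray,
    covariates: pd.DataFrame | None,
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, int, np.ndarray]:
    """Permutation estimate of the number of independent SNPs in a region.

    Permutes the phenotype B times, records the minimum SNP-association
    p-value across the region each time, takes the 5th percentile
    (nearest-rank, lower) as the regional threshold and reports
    floor(0.05/p5) independent SNPs.  Returns (p5, effective_snps, minima).
    """
    genotypes = np.asarray(genotypes, dtype=float)
    if genotypes.ndim != 2 or genotypes.shape[1] < 1:
        raise ValueError("genotypes must be (n_samples, n_snps) with >= 1 SNP")
    if genotypes.shape[1] == 1:
        return 0.05, 1, np.array([])
    rng = np.random.default_rng(seed)
    mins = np.empty(B)
    for b in range(B):
        yp = rng.permutation(np.asarray(y, dtype=float))
        best = 1.0
        for j in range(genotypes.shape[1]):
            row = binary_logit_snp(yp, genotypes[:, j], covariates)
            if row.converged and np.isfinite(row.p_genotype):
                best = min(best, row.p_genotype)
        mins[b] = best
    p5 = nearest_rank_lower(mins, 0.05)
    eff, _ = effective_tests(p5)
    return p5, eff, mins
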