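"""Cohort statistics: chi-square, ANOVA, proportional-odds and SNP models."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from admixscan import datasets
from admixscan._logistic import fit_logistic
from admixscan.epi_stats import (
    binary_logit_snp,
    contingency_chisq,
    covariate_screen,
    oneway_anova,
    ordinal_logit,
    region_effective_snps,
)


class TestContingencyChisq:
    def test_vessel_disease_table(self):
        chi2, df, p = contingency_chisq(datasets.VESSEL_DISEASE_BY_GRADE)
        assert df == 6
        assert p == pytest.approx(3.29e-22, rel=5e-3)

    def test_race_ethnicity_table(self):
        chi2, df, p = contingency_chisq(datasets.RACE_ETHNICITY_BY_GRADE)
        assert df == 6
        assert p == pytest.approx(2.57e-2, rel=5e-3)

    def test_matches_summation_oracle(self, rng):
        t = rng.integers(5, 80, size=(3, 4))
        chi2, df, _ = contingency_chisq(t)
        E = np.outer(t.sum(1), t.sum(0)) / t.sum()
        assert chi2 == pytest.approx(((t - E) ** 2 / E).sum(), rel=1e-12)
        assert df == 6

    def test_independent_table_chi2_zero(self):
        t = np.outer([10, 20], [5, 15])  # rows proportional to margins
        chi2, _, p = contingency_chisq(t)
        assert chi2 == pytest.approx(0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_zero_margin_named(self):
        t = pd.DataFrame([[5, 0], [7, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="column.*'?b'?"):
            contingency_chisq(t)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            contingency_chisq(np.array([[1, 2]]))


class TestOnewayAnova:
    def test_hand_computed_sums_of_squares(self):
        # SSB = 13.5, MSW = 1 -> F = 13.5 on (1, 4) df
        f, df1, df2, p = oneway_anova([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert (f, df1, df2) == (pytest.approx(13.5), 1, 4)
        from scipy import stats

        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_identical_means(self):
        f, _, _, p = oneway_anova([np.array([1.0, 2, 3]), np.array([2.0, 2, 2])])
        assert f == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_within_group_permutation_invariant(self, rng):
        g1, g2 = rng.normal(size=12), rng.normal(1, 1, size=9)
        a = oneway_anova([g1, g2])
        b = oneway_anova([rng.permutation(g1), rng.permutation(g2)])
        assert a == pytest.approx(b)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            oneway_anova([np.array([1.0]), np.array([2.0, 3.0])])


def _ordinal_negll(params, X, g, levels):
    k = X.shape[1]
    beta, cuts = params[:k], np.sort(params[k:])
    lp = X @ beta
    cum = expit(cuts[None, :] - lp[:, None])
    cum = np.hstack([np.zeros((len(g), 1)), cum, np.ones((len(g), 1))])
    idx = np.searchsorted(levels, g)
    probs = cum[np.arange(len(g)), idx + 1] - cum[np.arange(len(g)), idx]
    return -np.log(np.clip(probs, 1e-12, None)).sum()


class TestOrdinalLogit:
    def test_two_by_two_closed_form(self):
        # counts [[30,10],[10,30]] -> log OR = ln 9
        x = np.r_[np.zeros(40), np.ones(40)]
        g = np.r_[np.zeros(30), np.ones(10), np.zeros(10), np.ones(30)]
        fit = ordinal_logit(g, pd.DataFrame({"x": x}))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(9), abs=1e-4)

    def test_k2_reduces_to_binary_logistic(self, rng):
        X = rng.normal(size=(250, 2))
        y = (rng.random(250) < expit(0.7 * X[:, 0] - 0.4 * X[:, 1])).astype(float)
        fo = ordinal_logit(y, pd.DataFrame(X, columns=["a", "b"]))
        fb = fit_logistic(np.column_stack([np.ones(250), X]), y)
        np.testing.assert_allclose(fo.beta, fb.beta[1:], atol=1e-6)
        assert fo.cutpoints[0] == pytest.approx(-fb.beta[0], abs=1e-6)

    def test_matches_brute_force_likelihood(self, rng):
        g = np.array([0, 1, 2, 3, 0, 2, 1, 3, 0, 1, 2, 0, 3, 1, 2, 0, 1, 2, 3, 0])
        x = rng.normal(size=(20, 1))
        fit = ordinal_logit(g, pd.DataFrame(x, columns=["x"]))
        res = minimize(_ordinal_negll, np.r_[0.0, -1.0, 0.0, 1.0],
                       args=(x, g, np.unique(g)), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert fit.beta[0] == pytest.approx(res.x[0], abs=1e-5)
        assert -fit.loglik == pytest.approx(res.fun, abs=1e-6)

    def test_race_contrasts_reference_hispanic(self, rng):
        n = 900
        race = rng.choice(["HISP", "CAUC", "AA"], size=n, p=[0.6, 0.3, 0.1])
        lp = -0.39 * (race == "CAUC") - 0.23 * (race == "AA")
        u = rng.random(n)
        cum = expit(np.array([-0.1, 0.6, 1.9])[None, :] - lp[:, None])
        g = (u[:, None] > cum).sum(axis=1)
        fit = ordinal_logit(g, pd.DataFrame({"race_ethnicity": race}))
        assert fit.terms == ["race_ethnicity[AA]", "race_ethnicity[CAUC]"]
        i = fit.terms.index("race_ethnicity[CAUC]")
        assert abs(fit.beta[i] - (-0.39)) <= 3 * fit.se[i]

    def test_null_covariate_near_zero(self, rng):
        g = rng.integers(0, 4, 400)
        x = rng.normal(size=400)
        fit = ordinal_logit(g, pd.DataFrame({"x": x}))
        assert abs(fit.beta[0]) <= 3 * fit.se[0]

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="two observed levels"):
            ordinal_logit(np.zeros(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_row_order_invariance(self, rng):
        g = rng.integers(0, 4, 200)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        a = ordinal_logit(g, X)
        perm = rng.permutation(200)
        b = ordinal_logit(g[perm], X.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-7)


class TestBinaryLogitSnp:
    def test_constant_genotype_na_with_reason(self):
        row = binary_logit_snp(np.r_[np.zeros(5), np.ones(5)], np.ones(10))
        assert not row.converged
        assert row.reason == "constant_genotype"
        assert np.isnan(row.p_genotype)

    def test_binary_genotype_log_odds_ratio(self):
        # 2x2 counts: geno=0 -> 40/10, geno=1 -> 15/35 ; log OR = ln((35/15)/(10/40))
        geno = np.r_[np.zeros(50), np.ones(50)]
        y = np.r_[np.zeros(40), np.ones(10), np.zeros(15), np.ones(35)]
        row = binary_logit_snp(y, geno)
        assert row.beta_genotype == pytest.approx(np.log((35 / 15) / (10 / 40)),
                                                  abs=1e-6)

    def test_covariates_carried_through(self, rng):
        n = 200
        covs = pd.DataFrame({"ev1": rng.normal(size=n), "age": rng.normal(70, 9, n)})
        geno = rng.binomial(2, 0.4, n).astype(float)
        y = (rng.random(n) < expit(0.5 * geno - 0.3)).astype(float)
        row = binary_logit_snp(y, geno, covs, snp_id="rs1")
        assert row.converged and set(row.covariate_beta) == {"ev1", "age"}

    def test_complete_case(self, rng):
        y = rng.integers(0, 2, 60).astype(float)
        geno = rng.binomial(2, 0.5, 60).astype(float)
        geno[5] = np.nan
        row = binary_logit_snp(y, geno)
        assert row.n_obs == 59


class TestCovariateScreen:
    def test_strong_effect_always_selected(self, rng):
        picked = 0
        for _ in range(20):
            x = rng.normal(size=500)
            y = (rng.random(500) < expit(1.0 * x)).astype(float)
            picked += covariate_screen(pd.DataFrame({"x": x}), y) == ["x"]
        assert picked >= 19

    def test_null_type_one_control(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.normal(size=200)
            y = rng.integers(0, 2, 200).astype(float)
            hits += len(covariate_screen(pd.DataFrame({"x": x}), y))
        # expect ~5 selections; allow 3 binomial SEs
        assert hits <= 0.05 * 100 + 3 * np.sqrt(100 * 0.05 * 0.95)

    def test_output_order_is_input_order(self, rng):
        n = 400
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = (rng.random(n) < expit(1.2 * a + 1.2 * b)).astype(float)
        sel = covariate_screen(pd.DataFrame({"b": b, "a": a}), y)
        assert sel == ["b", "a"]


class TestRegionEffectiveSnps:
    def test_single_snp_region(self):
        p5, eff, _ = region_effective_snps(np.r_[np.zeros(5), np.ones(5)],
                                           np.ones((10, 1)), None, B=50, seed=0)
        assert eff == 1

    def test_independent_null_snps(self, rng):
        # 10 independent SNPs, null phenotype: effective count near 10
        # (nearest-rank p5 at B=400 carries ~21% relative Monte-Carlo error)
        n, m = 300, 10
        geno = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        p5, eff, mins = region_effective_snps(y, geno, None, B=400, seed=1)
        q = 1 - 0.95 ** (1 / m)
        rel_se = (np.sqrt(0.05 * 0.95 / 400) / (m * (1 - q) ** (m - 1))) / q
        lo, hi = 0.975 * m * (1 - 3 * rel_se), 0.975 * m * (1 + 3 * rel_se)
        assert lo <= eff <= hi
        assert len(mins) == 400
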