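"""Epidemiological statistics on the published summary tables and a
simulated cohort.

First reproduces the printed chi-square associations of collateral grade
with vessel-disease severity and race-ethnicity from the study's summary
counts, and the corrected threshold implied by its 1931 effective tests.
Then fits the proportional-odds model of the Rentrop grade on a simulated
cohort; the recovered sex effect should sit near the generative value 0.59.
"""

from admixscan import datasets
from admixscan.epi_stats import contingency_chisq, ordinal_logit
from admixscan.scan import threshold_for_tests
from admixscan.simulate import SimConfig, simulate_cohort

chi2, df, p = contingency_chisq(datasets.VESSEL_DISEASE_BY_GRADE)
print(f"grade vs vessel-disease severity: chi2 = {chi2:.1f}, df = {df}, p = {p:.3g}")
chi2, df, p = contingency_chisq(datasets.RACE_ETHNICITY_BY_GRADE)
print(f"grade vs race-ethnicity:          chi2 = {chi2:.1f}, df = {df}, p = {p:.3g}")
print(f"overall collateral prevalence: {datasets.collateral_prevalence_pct():.1f}%")
print(f"0.05 threshold at {datasets.EFFECTIVE_TESTS_AFR} effective tests: "
      f"{threshold_for_tests(datasets.EFFECTIVE_TESTS_AFR):.3g}")

sim = simulate_cohort(SimConfig(n_individuals=2000, n_snps=300, seed=5))
dfc = sim.cohort.df
covs = dfc[["sex", "smoking", "diabetes", "race_ethnicity"]]
keep = covs["race_ethnicity"] != "unclassified"
fit = ordinal_logit(dfc.loc[keep, "rentrop_grade"], covs.loc[keep])
print("\nproportional-odds model of the Rentrop grade (simulated cohort):")
for term, b, se, pv in zip(fit.terms, fit.beta, fit.se, fit.p):
    print(f"  {term:28s} beta = {b:+.3f}  se = {se:.3f}  p = {pv:.3g}")
print("-> sex enters near its generative log-odds of 0.59 (men develop"
      " collaterals more often)")
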