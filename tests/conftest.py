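import numpy as np
import pandas as pd
import pytest

from admixscan.io_formats import CohortTable
from admixscan.simulate import (
    ANCESTRY_LABELS,
    SimConfig,
    sim_admixed_haplotypes,
    sim_binary_phenotype,
    sim_covariates,
    simulate_cohort,
    snp_map,
)
from admixscan.ancestry import GlobalAncestry, LocalAncestryField, global_from_local


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_individuals=120, n_snps=600, seed=42))


def truth_scan_inputs(cfg: SimConfig, seed: int | None = None):
    """Simulate ancestry truth + phenotype and package them as scan inputs
    (ancestry-inference noise excluded so scan properties are attributable).

    Uses the cheap no-allele path; returns (field, global, cohort, truth).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    _, truth, props = sim_admixed_haplotypes(cfg, None, rng, draw_alleles=False)
    cov = sim_covariates(cfg, props, rng)
    y = sim_binary_phenotype(truth, cfg, cov, rng)
    samples = [f"i{k}" for k in range(cfg.n_individuals)]
    cohort = CohortTable(
        pd.DataFrame(
            {"sample_id": samples, "collaterals": y.astype(float),
             "age": cov["age"], "sex": cov["sex"]}
        )
    )
    field = LocalAncestryField(truth.local_proportions(), samples, snp_map(cfg),
                               ANCESTRY_LABELS)
    return field, global_from_local(field), cohort, truth
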