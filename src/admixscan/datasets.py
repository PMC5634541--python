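"""Published summary counts from the coronary-collateralization cohort.

The pipeline was developed for a cohort of 868 obstructive-CAD patients
graded for coronary collaterals on the Rentrop scale.  Individual-level data
are not shipped; these are the printed summary tables, usable as inputs to
the contingency-table statistics and the worked examples.
"""

from __future__ import annotations

import pandas as pd

GRADE_LABELS = ["grade0", "grade1", "grade2", "grade3"]

#: maximum Rentrop grade counts over the full cohort of 868 patients
GRADE_COUNTS = pd.Series([404, 142, 205, 117], index=GRADE_LABELS, name="patients")

#: collateral grade by vessel-disease severity (21 of 868 patients lacked
#: CAD-extent information and are excluded; rows sum to 847)
VESSEL_DISEASE_BY_GRADE = pd.DataFrame(
    [[207, 33, 48, 26], [118, 39, 46, 39], [69, 65, 106, 51]],
    index=["1VD", "2VD", "3VD"],
    columns=GRADE_LABELS,
)

#: collateral grade by PCA-defined race-ethnicity (42 unclassified patients
#: excluded; rows sum to 826)
RACE_ETHNICITY_BY_GRADE = pd.DataFrame(
    [[47, 13, 23, 9], [129, 30, 61, 27], [202, 94, 114, 77]],
    index=["AA", "CAUC", "HISP"],
    columns=GRADE_LABELS,
)

#: effective-test counts estimated by phenotype permutation in the original
#: genome-wide analyses (per-ancestry min-P mode)
EFFECTIVE_TESTS_AFR = 1931
EFFECTIVE_TESTS_NAM = 1543


def collateral_prevalence_pct(grade_counts: pd.Series = GRADE_COUNTS) -> float:
    """Percent of patients with any collaterals (grade >= 1)."""
    return 100.0 * grade_counts[GRADE_LABELS[1:]].sum() / grade_counts.sum()


def grade_share_pct(grade: int, grade_counts: pd.Series = GRADE_COUNTS) -> float:
    """Percent of patients at one Rentrop grade."""
    return 100.0 * grade_counts[f"grade{grade}"] / grade_counts.sum()


def group_collateral_rate_pct(group: str,
                              table: pd.DataFrame = RACE_ETHNICITY_BY_GRADE) -> float:
    """Percent of a group's patients with any collaterals (grade >= 1)."""
    row = table.loc[group]
    return 100.0 * row[GRADE_LABELS[1:]].sum() / row.sum()
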