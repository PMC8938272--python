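"""Bundled clinical summary of the five melanoma ICI cohorts.

Per-cohort patient characteristics, treatment details and outcome counts for
the two prospective PRIMM cohorts (UK and NL) and the three smaller cohorts
(Manchester, Leeds, Barcelona): enrolment, previous systemic therapy, BRAF
mutation status, combination-ICI use, RECIST response at 6 months and the
binarized 12-month progression-free survival endpoint. These counts drive the
pairwise cohort-comparison Fisher tests and internal consistency checks.
"""

from __future__ import annotations

import pandas as pd

from .community import fisher_exact_test

COHORTS = ("PRIMM-UK", "PRIMM-NL", "Manchester", "Leeds", "Barcelona")

_ROWS = {
    "n": (55, 55, 25, 18, 12),
    "male": (36, 31, 16, 11, 6),
    "braf_mutant": (17, 30, 3, 8, 3),
    "previous_therapy": (11, 22, 7, 0, 1),
    "ppi": (14, 20, 4, 5, 1),
    "antibiotics": (9, 11, 4, 2, 0),
    "combination_ici": (29, 12, 2, 10, 1),
    "complete_response": (8, 6, 4, 2, 2),
    "partial_response": (16, 16, 6, 4, 1),
    "stable_disease": (9, 11, 3, 4, 2),
    "progressive_disease": (22, 22, 12, 8, 7),
    "pfs12_responders": (28, 30, 13, 8, 7),
}

#: dietary questionnaires completed among the prospectively recruited patients
DIETARY_AVAILABLE = 93
PROSPECTIVE_N = 110


def cohort_summary() -> pd.DataFrame:
    """Counts by cohort (columns) and characteristic (rows)."""
    return pd.DataFrame(_ROWS, index=COHORTS).T


def compare_cohorts(characteristic: str, cohort_a: str, cohort_b: str) -> float:
    """Two-sided Fisher exact p comparing a characteristic between two cohorts."""
    s = cohort_summary()
    a_yes = int(s.loc[characteristic, cohort_a])
    b_yes = int(s.loc[characteristic, cohort_b])
    a_n = int(s.loc["n", cohort_a])
    b_n = int(s.loc["n", cohort_b])
    return fisher_exact_test(a_yes, a_n - a_yes, b_yes, b_n - b_yes)


def consistency_summary() -> dict[str, float]:
    """Arithmetic identities the bundled table must satisfy.

    Response categories at 6 months partition each cohort, PFS12 responders
    and enrolment sum across cohorts, and the dietary-data availability
    fraction among prospectively recruited patients is 93/110.
    """
    s = cohort_summary()
    return {
        "total_enrolled": float(s.loc["n"].sum()),
        "total_pfs12_responders": float(s.loc["pfs12_responders"].sum()),
        "total_progressive_disease": float(s.loc["progressive_disease"].sum()),
        "dietary_available_pct": round(100.0 * DIETARY_AVAILABLE / PROSPECTIVE_N, 1),
    }
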