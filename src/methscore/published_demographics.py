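"""Published case/control demographic summaries for the two cohorts.

The discovery cohort (Generation Scotland, N=9,502; 1,626 MDD cases) and
the female-only replication cohort (ALSPAC mothers, N=565; 67 cases)
published their demographic comparisons as group counts and group
mean/SD/N summaries. Those summaries are sufficient statistics for the
tests reported alongside them — Pearson chi-square for categorical rows,
Welch t for continuous rows — so the statistics can be recomputed here
without access-controlled individual-level data.

Category counts exclude the Missing row where the published degrees of
freedom require that (GS smoking and education) and include it where they
require it (ALSPAC smoking and alcohol); all-zero categories are dropped
(ALSPAC education).
"""

from __future__ import annotations

import numpy as np

from .descriptive import ContingencyTable, SummaryStatsPair, pearson_chisq, welch_t

__all__ = [
    "GS_AGE",
    "GS_SEX",
    "GS_SMOKING",
    "GS_EDUCATION",
    "ALSPAC_SMOKING",
    "ALSPAC_ALCOHOL",
    "ALSPAC_EDUCATION",
    "recompute_published_statistics",
]

# Generation Scotland: cases (MDD) vs controls
GS_AGE = (
    SummaryStatsPair(mean=48.23, sd=12.05, n=1626),  # cases
    SummaryStatsPair(mean=50.16, sd=13.83, n=7876),  # controls
)
GS_SEX = ContingencyTable(
    np.array([[1163, 463], [4452, 3424]]),
    ("cases", "controls"),
    ("F", "M"),
)
# current / former <1y / former >1y / never (Missing excluded)
GS_SMOKING = ContingencyTable(
    np.array([[395, 47, 454, 696], [1215, 227, 2155, 4105]]),
    ("cases", "controls"),
    ("current", "former_lt1y", "former_gt1y", "never"),
)
# nine qualification categories (Missing excluded)
GS_EDUCATION = ContingencyTable(
    np.array(
        [
            [134, 51, 47, 4, 192, 150, 145, 334, 461],
            [634, 191, 380, 31, 968, 729, 646, 1561, 2190],
        ]
    ),
    ("cases", "controls"),
    (
        "none",
        "other",
        "school_leavers",
        "cse",
        "o_level",
        "a_level",
        "nvq",
        "professional",
        "degree",
    ),
)

# ALSPAC mothers: cases vs controls (Missing included where df requires)
ALSPAC_SMOKING = ContingencyTable(
    np.array([[9, 58, 0], [35, 462, 1]]),
    ("cases", "controls"),
    ("current", "never", "missing"),
)
ALSPAC_ALCOHOL = ContingencyTable(
    np.array([[5, 13, 13, 19, 17, 0], [39, 67, 92, 188, 111, 1]]),
    ("cases", "controls"),
    (
        "never",
        "monthly_or_less",
        "2_4_per_month",
        "2_3_per_week",
        "4plus_per_week",
        "missing",
    ),
)
# the no-qualification category is all-zero and is dropped before testing
ALSPAC_EDUCATION = ContingencyTable(
    np.array([[0, 8, 7, 19, 23, 10], [0, 26, 25, 162, 161, 124]]),
    ("cases", "controls"),
    ("none", "cse", "vocational", "o_level", "a_level", "degree"),
)


def recompute_published_statistics() -> dict[str, float]:
    """All seven test statistics recomputable from the published summaries."""
    t_age, _, _ = welch_t(*GS_AGE)
    out = {
        "gs_age_welch_t": t_age,
        "gs_sex_chisq": pearson_chisq(GS_SEX)[0],
        "gs_smoking_chisq": pearson_chisq(GS_SMOKING)[0],
        "gs_education_chisq": pearson_chisq(GS_EDUCATION)[0],
        "alspac_smoking_chisq": pearson_chisq(ALSPAC_SMOKING)[0],
        "alspac_alcohol_chisq": pearson_chisq(ALSPAC_ALCOHOL)[0],
        "alspac_education_chisq": pearson_chisq(
            ALSPAC_EDUCATION, drop_zero_categories=True
        )[0],
    }
    return out
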