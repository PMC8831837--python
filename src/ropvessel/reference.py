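"""Published per-stage summary statistics of the ROP screening cohort.

These are the printed cohort tables of the study this package
reimplements the measurement pipeline for: per-stage image counts and
per-stage median / min / max / mean +- SD of the four temporal vessel
variables, plus the printed pairwise Pearson correlations. They serve
two roles: as inputs to the summary-statistic ANOVA / Tukey analyses
(which are exact functions of n, mean, sd), and as the design
parameters of synthetic cohorts.

Angles are degrees, widths are pixels at 1600 x 1200 fundus resolution.
"""

from __future__ import annotations

import numpy as np

from .phantom import CohortSpec, GroupParams
from .stats import GroupSummary

__all__ = [
    "STAGES",
    "COHORT_COUNTS",
    "SUMMARY",
    "PRINTED_CORRELATIONS",
    "TOTAL_IMAGES",
    "reference_summaries",
    "reference_cohort_spec",
]

#: Stage labels, ordered by severity.
STAGES = ("no_rop", "stage1", "stage2", "stage3")

#: Patients / images / laterality per stage.
COHORT_COUNTS = {
    "no_rop": {"patients": 44, "images": 66, "os": 32, "od": 34},
    "stage1": {"patients": 19, "images": 28, "os": 13, "od": 15},
    "stage2": {"patients": 20, "images": 33, "os": 16, "od": 17},
    "stage3": {"patients": 35, "images": 49, "os": 31, "od": 18},
}

TOTAL_IMAGES = sum(v["images"] for v in COHORT_COUNTS.values())

#: variable -> stage -> (median, min, max, mean, sd); n is the image count.
SUMMARY = {
    "taa": {
        "no_rop": (122.44, 98.53, 150.80, 122.42, 10.02),
        "stage1": (117.12, 87.48, 139.76, 114.23, 14.95),
        "stage2": (112.48, 89.50, 135.30, 111.87, 10.52),
        "stage3": (92.15, 57.66, 134.28, 92.72, 13.93),
    },
    "tva": {
        "no_rop": (123.75, 88.62, 168.55, 123.96, 16.55),
        "stage1": (119.52, 87.51, 157.29, 120.79, 18.65),
        "stage2": (116.49, 84.14, 147.49, 115.26, 14.83),
        "stage3": (102.69, 65.14, 160.09, 102.86, 21.91),
    },
    "taw": {
        "no_rop": (4.31, 3.03, 5.20, 4.21, 0.51),
        "stage1": (4.29, 3.36, 5.18, 4.22, 0.49),
        "stage2": (4.04, 3.44, 5.07, 4.10, 0.39),
        "stage3": (4.59, 3.46, 5.99, 4.58, 0.59),
    },
    "tvw": {
        "no_rop": (5.66, 4.26, 7.03, 5.63, 0.60),
        "stage1": (5.75, 4.78, 6.75, 5.75, 0.52),
        "stage2": (5.59, 4.04, 6.97, 5.61, 0.68),
        "stage3": (6.29, 4.43, 6.98, 6.03, 0.65),
    },
}

#: Printed pairwise Pearson correlations over all 176 images.
PRINTED_CORRELATIONS = {
    ("taa", "tva"): 0.411,
    ("taw", "tvw"): 0.362,
    ("taa", "taw"): -0.162,
    ("taa", "tvw"): -0.282,
    ("tva", "taw"): -0.082,
}


def reference_summaries(variable: str) -> list[GroupSummary]:
    """Published summary rows of one variable as GroupSummary objects."""
    rows = SUMMARY[variable]
    return [
        GroupSummary(
            label=stage,
            n=COHORT_COUNTS[stage]["images"],
            median=rows[stage][0],
            min=rows[stage][1],
            max=rows[stage][2],
            mean=rows[stage][3],
            sd=rows[stage][4],
        )
        for stage in STAGES
    ]


def reference_cohort_spec(
    variables=("taa", "tva", "taw", "tvw"),
    n_scale: float = 1.0,
    correlation: np.ndarray | None = None,
    seed: int = 0,
) -> CohortSpec:
    """CohortSpec with the published group sizes, means and SDs.

    ``n_scale`` multiplies every group size (for law-of-large-numbers
    checks); ``correlation`` optionally imposes a joint correlation
    among the chosen variables within each group.
    """
    groups = {
        stage: GroupParams(
            n=max(2, int(round(COHORT_COUNTS[stage]["images"] * n_scale))),
            mean={v: SUMMARY[v][stage][3] for v in variables},
            sd={v: SUMMARY[v][stage][4] for v in variables},
        )
        for stage in STAGES
    }
    return CohortSpec(groups=groups, correlation=correlation,
                      variables=tuple(variables), seed=seed)
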