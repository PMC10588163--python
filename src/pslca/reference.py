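"""Published TLGS baseline distribution used for calibration and fixtures.

The Tehran Lipid and Glucose Study (TLGS) smoking/metabolic-syndrome cohort
itself is not publicly deposited; what is public is its baseline table —
per-exposure-group counts for every confounder level and the age mean/SD.
Those printed summaries are encoded here and serve two purposes:

* calibration targets for the synthetic generator defaults, and
* a deterministic fixture cohort whose marginal distributions exactly equal
  the printed counts, sufficient for recomputing the published standardized
  differences (which depend only on per-group marginals).

Counts are (smokers, non-smokers); group sizes 512 and 4345 (n = 4857).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    DEFAULT_SCHEMA,
    EDUCATION_LEVELS,
    ITEM_COLUMNS,
    MARITAL_LEVELS,
    OCCUPATION_LEVELS,
)

N_EXPOSED = 512
N_UNEXPOSED = 4345
N_TOTAL = N_EXPOSED + N_UNEXPOSED

#: gender counts are "male" (the table prints female: 74 / 2885)
BASELINE_COUNTS = {
    "gender": {1: (438, 1460), 0: (74, 2885)},
    "marital_status": {
        "single": (102, 918),
        "married": (391, 3233),
        "divorced": (13, 56),
        "widowed": (6, 138),
    },
    "education": {
        "elementary": (57, 592),
        "secondary_school": (98, 641),
        "high_school": (264, 2067),
        "associate": (31, 284),
        "bsc": (56, 653),
        "msc_plus": (6, 108),
    },
    "occupation": {
        "employed": (378, 1606),
        "student": (11, 291),
        "housewife": (51, 2039),
        "no_work_with_income": (46, 325),
        "other": (26, 84),
    },
    "physical_activity": {1: (310, 2812), 0: (202, 1533)},
}

AGE_SUMMARY = {"exposed": (40.89, 12.67), "unexposed": (38.89, 13.56)}

#: marginal targets quoted in the source: 60.9% female, 10.5% smokers
MARGINAL_TARGETS = {"p_female": 0.609, "p_exposed": 0.105}


def marginal_level_probabilities(variable: str) -> dict:
    """Whole-cohort level probabilities implied by the baseline counts."""
    counts = BASELINE_COUNTS[variable]
    return {lev: (e + u) / N_TOTAL for lev, (e, u) in counts.items()}


def _fill_column(levels_counts: dict, n: int, group_idx: int) -> np.ndarray:
    out = []
    for lev, counts in levels_counts.items():
        out.extend([lev] * counts[group_idx])
    if len(out) != n:
        raise ValueError("counts do not sum to the group size")
    return np.asarray(out)


def reference_cohort() -> CohortTable:
    """Deterministic 4857-row cohort matching every printed baseline count.

    Columns are filled independently within exposure group (joint structure
    is not published and is irrelevant to marginal balance statistics). Age
    is a deterministic normal-quantile sequence with the printed group
    mean/SD, so its sample moments approximate — but do not exactly equal —
    the printed summaries.
    """
    from scipy import stats

    frames = []
    for gi, (n, exposure) in enumerate([(N_EXPOSED, 1), (N_UNEXPOSED, 0)]):
        mean, sd = AGE_SUMMARY["exposed" if exposure else "unexposed"]
        q = (np.arange(n) + 0.5) / n
        frames.append(
            pd.DataFrame(
                {
                    "exposure": exposure,
                    "gender": _fill_column(BASELINE_COUNTS["gender"], n, gi),
                    "age": mean + sd * stats.norm.ppf(q),
                    "marital_status": _fill_column(
                        BASELINE_COUNTS["marital_status"], n, gi
                    ),
                    "education": _fill_column(BASELINE_COUNTS["education"], n, gi),
                    "occupation": _fill_column(BASELINE_COUNTS["occupation"], n, gi),
                    "physical_activity": _fill_column(
                        BASELINE_COUNTS["physical_activity"], n, gi
                    ),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", [f"r{i:05d}" for i in range(len(df))])
    df["gender"] = df["gender"].astype(int)
    df["physical_activity"] = df["physical_activity"].astype(int)
    return CohortTable(df=df, schema=DEFAULT_SCHEMA)
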