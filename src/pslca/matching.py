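"""1:1 nearest-neighbour propensity-score matching without replacement.

This is the ATT design: each exposed subject is matched to the unexposed
subject with the nearest propensity score, provided the distance is within
a caliper; once used, an unexposed subject cannot be matched again.

The greedy processing order is deterministic and documented: exposed
subjects are processed in descending p̂ (hard-to-match high-propensity
subjects first), ties broken by ascending subject id; candidate ties at
equal distance also go to the ascending id. The caliper defaults to ±0.05
on the raw probability scale; a caliper of k·SD(logit p̂) can be computed
(and used by matching on the logit scale) via ``caliper_from_logit_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .cohort import EXPOSURE, PAIR_ID, SUBJECT_ID, CohortTable


@dataclass
class MatchedSet:
    """Matched exposed–unexposed pairs under a caliper."""

    pairs: pd.DataFrame  # exposed_id, unexposed_id, delta_ps
    caliper: float
    caliper_scale: str  # "ps" | "logit_sd"
    unmatched_exposed: list

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def caliper_from_logit_sd(propensity: np.ndarray, k: float = 0.2) -> float:
    """k × sample SD (n−1 denominator) of logit(p̂), the conventional caliper."""
    p = np.asarray(propensity, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 subjects")
    return float(k * np.std(logit(p), ddof=1))


def match_nearest(
    propensity: np.ndarray,
    exposure: np.ndarray,
    subject_ids=None,
    caliper: float = 0.05,
    scale: str = "ps",
) -> MatchedSet:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Parameters
    ----------
    propensity, exposure : arrays of p̂ and 0/1 exposure per subject.
    subject_ids : optional id tokens; defaults to stringified positions.
    caliper : maximum allowed |Δ| between matched scores (must be > 0).
    scale : ``"ps"`` matches on raw p̂; ``"logit_sd"`` matches on logit(p̂)
        with the caliper interpreted on the logit scale.
    """
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    p = np.asarray(propensity, dtype=float)
    e = np.asarray(exposure).astype(int)
    if e.sum() == 0 or e.sum() == len(e):
        raise ValueError("both exposure groups must be non-empty")
    ids = (
        np.asarray(subject_ids, dtype=object)
        if subject_ids is not None
        else np.array([str(i) for i in range(len(p))], dtype=object)
    )
    score = logit(p) if scale == "logit_sd" else p

    exp_idx = np.flatnonzero(e == 1)
    une_idx = np.flatnonzero(e == 0)
    # descending p̂, ties by ascending id (lexsort keys: last is primary)
    order = np.lexsort((ids[exp_idx], -score[exp_idx]))
    exp_idx = exp_idx[order]

    avail = np.ones(len(une_idx), dtype=bool)
    u_score = score[une_idx]
    u_ids = ids[une_idx]
    rows, unmatched = [], []
    for i in exp_idx:
        if not avail.any():
            unmatched.append(ids[i])
            continue
        d = np.abs(u_score - score[i])
        d_avail = np.where(avail, d, np.inf)
        best = d_avail.min()
        if best > caliper:
            unmatched.append(ids[i])
            continue
        cands = np.flatnonzero(d_avail == best)
        j = cands[np.argsort(u_ids[cands].astype(str))[0]]
        avail[j] = False
        rows.append((ids[i], u_ids[j], float(best)))
    pairs = pd.DataFrame(rows, columns=["exposed_id", "unexposed_id", "delta_ps"])
    return MatchedSet(
        pairs=pairs, caliper=caliper, caliper_scale=scale, unmatched_exposed=unmatched
    )


def matched_cohort(matched: MatchedSet, cohort: CohortTable) -> CohortTable:
    """Restrict a cohort to matched subjects, adding a pair identifier column."""
    df = cohort.df.set_index(SUBJECT_ID, drop=False)
    missing = [
        sid
        for col in ("exposed_id", "unexposed_id")
        for sid in matched.pairs[col]
        if sid not in df.index
    ]
    if missing:
        raise KeyError(f"dangling subject id(s) in matched set: {missing[:5]}")
    blocks = []
    for k, row in enumerate(matched.pairs.itertuples(index=False)):
        block = df.loc[[row.exposed_id, row.unexposed_id]].copy()
        block[PAIR_ID] = k
        blocks.append(block)
    if blocks:
        out = pd.concat(blocks, ignore_index=True)
    else:
        out = cohort.df.iloc[0:0].copy()
        out[PAIR_ID] = pd.Series(dtype=int)
    return CohortTable(df=out, schema=cohort.schema)
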