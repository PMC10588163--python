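"""Standardized differences for covariate balance before and after adjustment.

For a continuous confounder the standardized difference is

    d = (x̄_exposed − x̄_unexposed) / sqrt((s²_exposed + s²_unexposed) / 2)

and for a binary confounder

    d = (p̂_e − p̂_u) / sqrt((p̂_e(1−p̂_e) + p̂_u(1−p̂_u)) / 2),

reported as absolute values; d < 0.1 is the conventional balance threshold.
The weighted variants substitute weighted means, proportions and variances
(weighted variance uses the frequency-weight convention
Σw(x−x̄_w)²/(Σw−1), which reduces exactly to the unweighted formula at unit
weights). Categorical confounders are checked level-by-level as binary
indicators against their reference level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import AGE, EXPOSURE, DEFAULT_REFERENCES, CohortTable

BALANCE_THRESHOLD = 0.1


def _wmean(x, w):
    return np.sum(w * x) / np.sum(w)


def _wvar(x, w):
    m = _wmean(x, w)
    return np.sum(w * (x - m) ** 2) / (np.sum(w) - 1.0)


def std_diff_continuous(x, exposure, weights=None, signed: bool = False) -> float:
    """Standardized difference in means of a continuous covariate."""
    x = np.asarray(x, dtype=float)
    e = np.asarray(exposure).astype(bool)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    if e.sum() < 2 or (~e).sum() < 2:
        raise ValueError("each exposure group needs at least 2 subjects")
    m1, m0 = _wmean(x[e], w[e]), _wmean(x[~e], w[~e])
    v1, v0 = _wvar(x[e], w[e]), _wvar(x[~e], w[~e])
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        raise ValueError("zero pooled variance")
    d = (m1 - m0) / denom
    return float(d) if signed else float(abs(d))


def std_diff_continuous_from_stats(m1, s1, m0, s0, signed: bool = False) -> float:
    """Same formula evaluated from published group summaries (mean, SD)."""
    d = (m1 - m0) / np.sqrt((s1**2 + s0**2) / 2.0)
    return float(d) if signed else float(abs(d))


def std_diff_binary(x, exposure, weights=None, signed: bool = False) -> float:
    """Standardized difference in proportions of a binary covariate."""
    x = np.asarray(x, dtype=float)
    e = np.asarray(exposure).astype(bool)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    if e.sum() == 0 or (~e).sum() == 0:
        raise ValueError("both exposure groups must be non-empty")
    p1, p0 = _wmean(x[e], w[e]), _wmean(x[~e], w[~e])
    denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    if denom == 0:
        raise ValueError("zero denominator: both proportions are degenerate")
    d = (p1 - p0) / denom
    return float(d) if signed else float(abs(d))


def std_diff_binary_from_counts(k1, n1, k0, n0, signed: bool = False) -> float:
    """Binary standardized difference from published per-group counts."""
    p1, p0 = k1 / n1, k0 / n0
    d = (p1 - p0) / np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    return float(d) if signed else float(abs(d))


@dataclass
class BalanceTable:
    """Per-confounder standardized differences across analysis datasets."""

    table: pd.DataFrame

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        """Report view: d columns rounded (round-half-even) to ``decimals``."""
        out = self.table.copy()
        for c in out.columns:
            if c.startswith("d_"):
                out[c] = out[c].round(decimals)
        return out


def _balance_rows(cohort: CohortTable, confounders, references):
    """Yield (confounder, level, values-array, kind) per balance row."""
    df = cohort.df
    schema = cohort.schema
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    for cov in confounders:
        if cov in schema.categorical_levels:
            levels = schema.categorical_levels[cov]
            ref = refs[cov]
            for lev in levels:
                if lev == ref:
                    continue
                yield cov, lev, None, "binary"
        elif cov in schema.continuous_columns:
            yield cov, "—", None, "continuous"
        else:
            yield cov, "—", None, "binary"


def _row_values(cohort: CohortTable, cov: str, lev: str) -> np.ndarray:
    df = cohort.df
    if lev == "—":
        return df[cov].to_numpy(dtype=float)
    return (df[cov] == lev).to_numpy(dtype=float)


def balance_table(
    cohort: CohortTable,
    confounders: Sequence[str],
    weights: np.ndarray | None = None,
    matched: CohortTable | None = None,
    references=None,
    threshold: float = BALANCE_THRESHOLD,
) -> BalanceTable:
    """Standardized differences in the original, weighted and matched data.

    One row per binary/continuous confounder and per non-reference level of
    each categorical; absolute values with a ≥ threshold flag per dataset.
    Weighted and matched columns appear only when the corresponding input is
    supplied.
    """
    exposure = cohort.df[EXPOSURE].to_numpy()

    def _d(fn, *args, **kw):
        # a level absent from both groups has an undefined d; report NaN
        try:
            return fn(*args, **kw)
        except ValueError:
            return np.nan

    rows = []
    for cov, lev, _, kind in _balance_rows(cohort, confounders, references):
        fn = std_diff_continuous if kind == "continuous" else std_diff_binary
        x = _row_values(cohort, cov, lev)
        rec = {"confounder": cov, "level": lev}
        rec["d_original"] = _d(fn, x, exposure)
        if weights is not None:
            rec["d_weighted"] = _d(fn, x, exposure, weights=weights)
        if matched is not None:
            xm = _row_values(matched, cov, lev)
            em = matched.df[EXPOSURE].to_numpy()
            rec["d_matched"] = _d(fn, xm, em)
        rows.append(rec)
    table = pd.DataFrame(rows)
    for c in [c for c in table.columns if c.startswith("d_")]:
        table[f"flag_{c[2:]}"] = table[c] >= threshold
    return BalanceTable(table=table)
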