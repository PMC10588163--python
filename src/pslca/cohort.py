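"""Cohort data model, delimited I/O, validation, and design-matrix encoding.

Analyses in this package operate on a subject-level cohort table with a
binary exposure (daily smoking), six measured confounders (gender, age,
marital status, education, occupation, physical activity) and five binary
metabolic-syndrome indicators (abdominal obesity, impaired fasting glucose,
hypertriglyceridemia, hypertension, low HDL cholesterol).

The file format is plain CSV (UTF-8, header row required); binary variables
are encoded 0/1 only, categorical variables as lower-case level tokens.
Missing values are a hard error: the analysis is complete-case by design.

Item columns are optional at the baseline stage (exposure/confounder work)
and become required before the latent-class stage, mirroring a two-phase
cohort in which the outcome indicators are measured at a later visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

SUBJECT_ID = "subject_id"
EXPOSURE = "exposure"
AGE = "age"
WEIGHT = "weight"
PAIR_ID = "pair_id"

MARITAL_LEVELS = ("single", "married", "divorced", "widowed")
EDUCATION_LEVELS = (
    "elementary",
    "secondary_school",
    "high_school",
    "associate",
    "bsc",
    "msc_plus",
)
OCCUPATION_LEVELS = (
    "employed",
    "student",
    "housewife",
    "no_work_with_income",
    "other",
)

ITEM_COLUMNS = ("item_1", "item_2", "item_3", "item_4", "item_5")

#: What each indicator measures (fixed item order used everywhere).
ITEM_DESCRIPTIONS = {
    "item_1": "abdominal_obesity",
    "item_2": "impaired_fasting_glucose",
    "item_3": "hypertriglyceridemia",
    "item_4": "hypertension",
    "item_5": "low_hdl",
}

CONFOUNDERS = (
    "gender",
    "age",
    "marital_status",
    "education",
    "occupation",
    "physical_activity",
)

#: Modal levels in the source population; conventional reference coding.
DEFAULT_REFERENCES = {
    "marital_status": "married",
    "education": "high_school",
    "occupation": "employed",
}


@dataclass(frozen=True)
class CohortSchema:
    """Declares the level sets and binary/continuous typing of a cohort file."""

    categorical_levels: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "marital_status": MARITAL_LEVELS,
            "education": EDUCATION_LEVELS,
            "occupation": OCCUPATION_LEVELS,
        }
    )
    binary_columns: tuple = ("exposure", "gender", "physical_activity") + ITEM_COLUMNS
    continuous_columns: tuple = (AGE,)

    def required_columns(self, stage: str = "baseline") -> tuple:
        """Columns that must be present and complete at a pipeline stage.

        ``baseline`` requires exposure and confounders; ``lca`` additionally
        requires the five indicator columns.
        """
        base = (SUBJECT_ID, EXPOSURE) + CONFOUNDERS
        if stage == "baseline":
            return base
        if stage == "lca":
            return base + ITEM_COLUMNS
        raise ValueError(f"unknown stage {stage!r} (use 'baseline' or 'lca')")


DEFAULT_SCHEMA = CohortSchema()


@dataclass
class CohortTable:
    """A validated subject-level cohort backed by a pandas DataFrame."""

    df: pd.DataFrame
    schema: CohortSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list:
        return list(self.df.columns)

    def weights(self) -> np.ndarray:
        """Per-subject weight column, defaulting to 1.0 when absent."""
        if WEIGHT in self.df.columns:
            return self.df[WEIGHT].to_numpy(dtype=float)
        return np.ones(len(self.df))

    def with_weights(self, w: np.ndarray) -> "CohortTable":
        df = self.df.copy()
        df[WEIGHT] = np.asarray(w, dtype=float)
        return replace(self, df=df)

    def write(self, path) -> None:
        write_cohort(self, path)


def _to_float(series: pd.Series) -> pd.Series:
    """Correctly-rounded string→float64 coercion; unparseable values → NaN.

    (pandas' fast ``to_numeric`` parser is not correctly rounding, which
    would break bit-exact file round-trips.)
    """

    def conv(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        try:
            return np.float64(v)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv).astype(float)


def _coerce_types(df: pd.DataFrame, schema: CohortSchema) -> pd.DataFrame:
    df = df.copy()
    numeric = schema.binary_columns + schema.continuous_columns + (WEIGHT,)
    for col in numeric:
        if col in df.columns:
            df[col] = _to_float(df[col])
    if SUBJECT_ID in df.columns:
        df[SUBJECT_ID] = df[SUBJECT_ID].astype(str)
    return df


def validate_cohort(
    df: pd.DataFrame,
    schema: CohortSchema = DEFAULT_SCHEMA,
    stage: str = "baseline",
) -> None:
    """Check every declared invariant, reporting all violating rows at once.

    Raises
    ------
    SchemaError
        If a column required for `stage` is absent.
    CohortValidationError
        Listing (row, column, message) for every violation found.
    """
    required = schema.required_columns(stage)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    failures: list = []

    def _flag(mask, col, msg):
        for idx in df.index[np.asarray(mask, dtype=bool)]:
            failures.append((idx, col, msg))

    for col in required:
        vals = df[col]
        if vals.isna().any():
            _flag(vals.isna(), col, "missing value in required column")

    if df[SUBJECT_ID].duplicated().any():
        _flag(df[SUBJECT_ID].duplicated(), SUBJECT_ID, "duplicate subject id")

    for col in schema.binary_columns:
        if col not in df.columns or col not in required:
            continue
        vals = df[col]
        bad = vals.notna() & ~vals.isin([0, 1])
        if bad.any():
            _flag(bad, col, "binary column must be 0 or 1")

    if AGE in df.columns:
        vals = df[AGE]
        bad = vals.notna() & ~(np.isfinite(vals) & (vals > 0))
        if bad.any():
            _flag(bad, AGE, "age must be finite and > 0")

    for col, levels in schema.categorical_levels.items():
        if col not in df.columns:
            continue
        vals = df[col]
        bad = vals.notna() & ~vals.isin(levels)
        if bad.any():
            _flag(bad, col, f"value outside declared levels {levels}")

    if WEIGHT in df.columns:
        vals = df[WEIGHT]
        bad = vals.notna() & ~(vals > 0)
        if bad.any():
            _flag(bad, WEIGHT, "weight must be > 0")

    if failures:
        raise CohortValidationError(sorted(failures))


def read_cohort(
    path,
    schema: CohortSchema = DEFAULT_SCHEMA,
    stage: str = "baseline",
) -> CohortTable:
    """Read and validate a CSV cohort file.

    Values are coerced to declared types; any invariant violation raises with
    the offending row indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    df = _coerce_types(df, schema)
    validate_cohort(df, schema, stage=stage)
    # binary columns stored as integers after validation
    for col in schema.binary_columns:
        if col in df.columns and df[col].notna().all():
            df[col] = df[col].astype(int)
    return CohortTable(df=df, schema=schema)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV (UTF-8, header row, no index column)."""
    cohort.df.to_csv(path, index=False)


@dataclass
class DesignMatrix:
    """Numeric covariate matrix with explicit reference-level bookkeeping.

    Dummy coding is k−1: a k-level categorical expands to one indicator per
    non-reference level, in declared level order; binary and continuous
    covariates pass through unchanged. Column order follows the covariate
    declaration order, so encodings are deterministic.
    """

    columns: list
    matrix: np.ndarray
    references: dict

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_degenerate(self) -> bool:
        """True when the columns (with an implicit intercept) are rank-deficient."""
        X = np.column_stack([np.ones(self.matrix.shape[0]), self.matrix])
        return np.linalg.matrix_rank(X) < X.shape[1]

    def correlation_matrix(self) -> pd.DataFrame:
        r = np.corrcoef(self.matrix, rowvar=False)
        return pd.DataFrame(r, index=self.columns, columns=self.columns)


def encode_design(
    cohort: CohortTable,
    covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> DesignMatrix:
    """Build the covariate matrix entering the exposure (propensity) model."""
    df = cohort.df
    schema = cohort.schema
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)

    names: list = []
    cols: list = []
    used_refs: dict = {}
    for cov in covariates:
        if cov not in df.columns:
            raise SchemaError(f"unknown covariate {cov!r}")
        if cov in schema.categorical_levels:
            levels = schema.categorical_levels[cov]
            ref = refs.get(cov)
            if ref not in levels:
                raise SchemaError(
                    f"reference {ref!r} not in declared levels of {cov!r}"
                )
            used_refs[cov] = ref
            for lev in levels:
                if lev == ref:
                    continue
                names.append(f"{cov}[{lev}]")
                cols.append((df[cov] == lev).to_numpy(dtype=float))
        else:
            names.append(cov)
            cols.append(df[cov].to_numpy(dtype=float))
    matrix = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return DesignMatrix(columns=names, matrix=matrix, references=used_refs)
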