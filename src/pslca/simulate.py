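"""Synthetic cohort generator with recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, in three stages:

1. confounders drawn from declared categorical probability vectors and a
   truncated-normal age distribution (defaults calibrated to the published
   TLGS baseline table, see :mod:`pslca.reference`);
2. a logistic exposure model: smoking ~ Bernoulli(expit(β₀ + xβ)), with the
   per-subject linear predictor built from the same design encoding the
   propensity model later uses — the recorded true propensity is therefore
   exactly the quantity the propensity module estimates;
3. a multinomial-logit latent-class membership model on exposure (and,
   optionally, confounder columns — the confounding knob), followed by
   class-conditional independent Bernoulli indicators with item-response
   probabilities ``rho_true``.

Because class membership is multinomial-logit — the same family the effect
estimator assumes — the true conditional odds ratios are exactly the
exponentiated exposure coefficients; when confounders also enter the class
model the marginal (ATE) odds ratios differ by non-collapsibility and are
computed by :func:`true_marginal_or`.

A single master seed expands deterministically into per-stage child seeds
(``numpy.random.SeedSequence(seed).spawn``), so stages can be regenerated
independently and every generated cell is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import reference
from .cohort import (
    CohortTable,
    DEFAULT_SCHEMA,
    EXPOSURE,
    ITEM_COLUMNS,
    encode_design,
)
from .errors import SchemaError

_N_ITEMS = len(ITEM_COLUMNS)


@dataclass
class GeneratorSpec:
    """Full parameterization of one synthetic-cohort scenario."""

    n: int
    seed: int
    # --- confounder distributions ---
    p_male: float
    age_mean: float
    age_sd: float
    age_range: tuple = (20.0, 90.0)
    marital_probs: Mapping[str, float] = field(default_factory=dict)
    education_probs: Mapping[str, float] = field(default_factory=dict)
    occupation_probs: Mapping[str, float] = field(default_factory=dict)
    p_active: float = 0.5
    # --- exposure model (log-odds on design columns) ---
    exposure_intercept: float = 0.0
    exposure_coefs: Mapping[str, float] = field(default_factory=dict)
    # --- latent-class membership model ---
    n_classes: int = 1
    class_intercepts: tuple = ()
    class_exposure_coefs: tuple = ()
    class_confounder_coefs: Mapping[str, tuple] = field(default_factory=dict)
    rho_true: np.ndarray | None = None

    def __post_init__(self):
        for probs in (self.marital_probs, self.education_probs, self.occupation_probs):
            if probs and abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("categorical probability vector must sum to 1")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.rho_true is not None:
            self.rho_true = np.asarray(self.rho_true, dtype=float)
            if self.rho_true.shape != (self.n_classes, _N_ITEMS):
                raise ValueError(
                    f"rho_true must be {self.n_classes}x{_N_ITEMS}, "
                    f"got {self.rho_true.shape}"
                )
            if not np.all((self.rho_true > 0) & (self.rho_true < 1)):
                raise ValueError("rho_true entries must lie strictly in (0, 1)")
        if len(self.class_intercepts) != self.n_classes - 1:
            raise ValueError("class_intercepts must have length n_classes - 1")
        if len(self.class_exposure_coefs) != self.n_classes - 1:
            raise ValueError("class_exposure_coefs must have length n_classes - 1")

    def stage_rngs(self):
        """Per-stage child generators (confounders, exposure, classes)."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated cohort."""

    spec: GeneratorSpec
    true_propensity: np.ndarray | None = None
    true_class: np.ndarray | None = None  # 1-based, in {1..C*}
    exposure: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        data = {}
        if self.true_propensity is not None:
            data["true_propensity"] = self.true_propensity
        if self.true_class is not None:
            data["true_class"] = self.true_class
        if self.exposure is not None:
            data["exposure"] = self.exposure
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# default scenario ("tlgs_like")
# --------------------------------------------------------------------------

#: Item-response probabilities of the three latent metabolic-syndrome classes
#: (rows: no-syndrome, low risk, moderate risk; columns: abdominal obesity,
#: impaired glucose, hypertriglyceridemia, hypertension, low HDL). The rows
#: follow the qualitative structure of the published solutions — a class low
#: on every component, a low-risk class driven by abdominal obesity, and a
#: moderate-risk class driven by hypertriglyceridemia plus low HDL — with
#: between-class separation strong enough that the class structure is
#: recoverable at the default sample size (weakly separated classes are not
#: estimable to useful precision at n of a few thousand).
RHO_TLGS_LIKE = np.array(
    [
        [0.03, 0.05, 0.03, 0.05, 0.05],
        [0.95, 0.35, 0.10, 0.35, 0.15],
        [0.25, 0.25, 0.95, 0.15, 0.92],
    ]
)

#: True conditional exposure→class odds ratios of the default scenario
#: (low risk vs none, moderate vs none).
TRUE_CLASS_ORS = (1.45, 1.68)

#: Exposure-model intercept calibrated (by numerical averaging over the
#: default confounder distribution) so that marginal smoking prevalence is
#: the published 10.5%.
_TLGS_EXPOSURE_INTERCEPT = -4.0534

#: Log-odds of smoking per design column in the default scenario: smoking is
#: strongly male-predominant, mildly increasing with age, slightly less
#: common among the physically active.
_TLGS_EXPOSURE_COEFS = {"gender": 2.46, "age": 0.012, "physical_activity": -0.18}


def tlgs_like(
    n: int = 4857,
    seed: int = 0,
    confounded: bool = False,
    class_exposure_log_or: tuple | None = None,
) -> GeneratorSpec:
    """Default scenario: a cohort shaped like the published baseline table.

    Three latent classes with base prevalences ≈ (0.30, 0.36, 0.34) — the
    shares of the published matched-data three-class solution — and exposure
    odds ratios ``TRUE_CLASS_ORS`` on class membership. With
    ``confounded=True``, gender also enters the class model (log-odds 0.8
    for both at-risk classes), making the crude exposure–class association
    biased while IPTW/matching remain consistent.
    """
    if class_exposure_log_or is None:
        class_exposure_log_or = tuple(np.log(TRUE_CLASS_ORS))
    return GeneratorSpec(
        n=n,
        seed=seed,
        p_male=1.0 - reference.MARGINAL_TARGETS["p_female"],
        age_mean=39.10,
        age_sd=13.48,
        marital_probs=reference.marginal_level_probabilities("marital_status"),
        education_probs=reference.marginal_level_probabilities("education"),
        occupation_probs=reference.marginal_level_probabilities("occupation"),
        p_active=reference.marginal_level_probabilities("physical_activity")[1],
        exposure_intercept=_TLGS_EXPOSURE_INTERCEPT,
        exposure_coefs=dict(_TLGS_EXPOSURE_COEFS),
        n_classes=3,
        class_intercepts=(np.log(0.36 / 0.30), np.log(0.34 / 0.30)),
        class_exposure_coefs=tuple(class_exposure_log_or),
        class_confounder_coefs={"gender": (0.8, 0.8)} if confounded else {},
        rho_true=RHO_TLGS_LIKE.copy(),
    )


# --------------------------------------------------------------------------
# generation stages
# --------------------------------------------------------------------------


def _draw_categorical(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs.keys())
    p = np.asarray([probs[l] for l in levels], dtype=float)
    idx = rng.choice(len(levels), size=n, p=p / p.sum())
    return np.asarray(levels, dtype=object)[idx]


def generate_confounders(spec: GeneratorSpec, rng=None) -> CohortTable:
    """Stage 1: draw the confounder block (no exposure, no items)."""
    if rng is None:
        rng = spec.stage_rngs()[0]
    n = spec.n
    lo, hi = spec.age_range
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i:06d}" for i in range(n)],
            "gender": (rng.random(n) < spec.p_male).astype(int),
            "age": age,
            "marital_status": _draw_categorical(rng, spec.marital_probs, n),
            "education": _draw_categorical(rng, spec.education_probs, n),
            "occupation": _draw_categorical(rng, spec.occupation_probs, n),
            "physical_activity": (rng.random(n) < spec.p_active).astype(int),
        }
    )
    return CohortTable(df=df, schema=DEFAULT_SCHEMA)


def _linear_predictor(
    cohort: CohortTable, intercept: float, coefs: Mapping[str, float]
) -> np.ndarray:
    """Intercept + Σ coef·column over design columns named by `coefs`.

    Keys may be raw columns (``age``) or dummy columns (``marital_status[single]``).
    """
    eta = np.full(len(cohort), float(intercept))
    if not coefs:
        return eta
    raw = [k for k in coefs if "[" not in k]
    dummies = [k for k in coefs if "[" in k]
    for k in raw:
        if k not in cohort.df.columns:
            raise SchemaError(f"exposure/class model names unknown column {k!r}")
        eta += coefs[k] * cohort.df[k].to_numpy(dtype=float)
    for k in dummies:
        col, lev = k[:-1].split("[")
        if col not in cohort.df.columns:
            raise SchemaError(f"exposure/class model names unknown column {col!r}")
        eta += coefs[k] * (cohort.df[col] == lev).to_numpy(dtype=float)
    return eta


def assign_exposure(
    cohort: CohortTable, spec: GeneratorSpec, rng=None
) -> tuple[CohortTable, np.ndarray]:
    """Stage 2: draw exposure ~ Bernoulli(expit(xβ)); return true propensity."""
    if rng is None:
        rng = spec.stage_rngs()[1]
    ps = expit(_linear_predictor(cohort, spec.exposure_intercept, spec.exposure_coefs))
    exposure = (rng.random(len(cohort)) < ps).astype(int)
    df = cohort.df.copy()
    df[EXPOSURE] = exposure
    return CohortTable(df=df, schema=cohort.schema), ps


def _class_probabilities(cohort: CohortTable, spec: GeneratorSpec) -> np.ndarray:
    """n × C* membership probabilities under the multinomial-logit model."""
    n, C = len(cohort), spec.n_classes
    eta = np.zeros((n, C))
    for c in range(1, C):
        coefs = {EXPOSURE: spec.class_exposure_coefs[c - 1]}
        for col, per_class in spec.class_confounder_coefs.items():
            coefs[col] = per_class[c - 1]
        eta[:, c] = _linear_predictor(cohort, spec.class_intercepts[c - 1], coefs)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def assign_classes_and_items(
    cohort: CohortTable,
    spec: GeneratorSpec,
    rng=None,
    true_propensity: np.ndarray | None = None,
) -> tuple[CohortTable, SyntheticTruth]:
    """Stage 3: draw latent class then class-conditional independent items."""
    if spec.rho_true is None:
        raise ValueError("spec.rho_true is required to generate items")
    if EXPOSURE not in cohort.df.columns:
        raise SchemaError("exposure must be assigned before classes/items")
    if rng is None:
        rng = spec.stage_rngs()[2]
    probs = _class_probabilities(cohort, spec)
    u = rng.random(len(cohort))
    true_class = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)  # 0-based
    items = (
        rng.random((len(cohort), _N_ITEMS)) < spec.rho_true[true_class]
    ).astype(int)
    df = cohort.df.copy()
    for j, col in enumerate(ITEM_COLUMNS):
        df[col] = items[:, j]
    truth = SyntheticTruth(
        spec=spec,
        true_propensity=true_propensity,
        true_class=true_class + 1,
        exposure=df[EXPOSURE].to_numpy(),
    )
    return CohortTable(df=df, schema=cohort.schema), truth


def simulate_cohort(spec: GeneratorSpec) -> tuple[CohortTable, SyntheticTruth]:
    """Run all three stages under the master seed."""
    r1, r2, r3 = spec.stage_rngs()
    cohort = generate_confounders(spec, rng=r1)
    cohort, ps = assign_exposure(cohort, spec, rng=r2)
    return assign_classes_and_items(cohort, spec, rng=r3, true_propensity=ps)


# --------------------------------------------------------------------------
# ground-truth effect summaries
# --------------------------------------------------------------------------


def true_marginal_or(spec: GeneratorSpec, cohort: CohortTable) -> np.ndarray:
    """Sample-level marginal (ATE) odds ratios of exposure on class membership.

    Averages the multinomial-logit class probabilities over the cohort's own
    confounders with exposure forced to 1 and to 0, then forms the odds
    ratios of each at-risk class versus the reference class. Without
    confounders in the class model this equals ``exp(class_exposure_coefs)``
    exactly; with them it is the non-collapsible marginal estimand that IPTW
    targets.
    """
    marg = {}
    df = cohort.df.copy()
    for x in (0, 1):
        df[EXPOSURE] = x
        marg[x] = _class_probabilities(
            CohortTable(df=df, schema=cohort.schema), spec
        ).mean(axis=0)
    p0, p1 = marg[0], marg[1]
    return (p1[1:] / p1[0]) / (p0[1:] / p0[0])


def calibrate_exposure_intercept(
    spec: GeneratorSpec, target_prevalence: float, n: int = 200_000, seed: int = 12345
) -> float:
    """Solve for the intercept giving a requested marginal exposure prevalence."""
    from scipy.optimize import brentq

    big = GeneratorSpec(
        **{
            **spec.__dict__,
            "n": n,
            "seed": seed,
            "rho_true": spec.rho_true,
        }
    )
    conf = generate_confounders(big)
    eta0 = _linear_predictor(conf, 0.0, spec.exposure_coefs)
    return brentq(
        lambda b0: expit(b0 + eta0).mean() - target_prevalence, -30.0, 30.0, xtol=1e-8
    )
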