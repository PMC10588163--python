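"""Propensity-score estimation, diagnostics, and ATE inverse-probability weights.

The propensity score p̂ is the probability of exposure (daily smoking) given
the measured confounders, estimated by maximum-likelihood logistic
regression. Age may enter through fractional-polynomial terms selected by
the Royston–Altman closed test. Diagnostics cover p̂ overlap between
exposure groups (histogram on shared bins) and predictor collinearity
(pairwise Pearson correlations, flagged at |r| ≥ 0.3).

ATE weights are the unstabilized inverse-probability weights
w = 1/p̂ (exposed) and 1/(1−p̂) (unexposed); no truncation is applied by
default, matching the convention of reporting raw weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .cohort import AGE, EXPOSURE, CohortTable, DesignMatrix, encode_design
from .errors import EstimationError

#: Standard fractional-polynomial power set; 0 denotes the log transform.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass
class PSFit:
    """Fitted exposure model and per-subject propensity scores."""

    coefficients: pd.Series  # index: const + design columns (+ FP terms)
    propensity: np.ndarray  # p̂ ∈ (0,1), one per subject
    exposure: np.ndarray
    age_powers: tuple | None = None  # chosen FP powers, () = age dropped
    converged: bool = True
    max_abs_correlation: float = np.nan
    fp_deviance_table: pd.DataFrame | None = None


@dataclass
class IPTWeights:
    """Unstabilized ATE weights: 1/p̂ for exposed, 1/(1−p̂) for unexposed."""

    weights: np.ndarray
    estimand: str = "ATE"


@dataclass
class OverlapReport:
    """Shared-bin histogram comparison of p̂ between exposure groups."""

    bin_edges: np.ndarray
    counts_exposed: np.ndarray
    counts_unexposed: np.ndarray
    range_exposed: tuple
    range_unexposed: tuple
    frac_exposed_outside: float
    frac_unexposed_outside: float
    adequate: bool


def _fit_logistic(X: np.ndarray, names: Sequence[str], y: np.ndarray):
    """MLE logistic fit with rank and separation checks.

    Returns (params Series, fitted probabilities, −2·loglik).
    """
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name a column involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(Xc)
        diag = np.abs(np.diag(r))
        bad = int(np.argmin(diag))
        label = (["const"] + list(names))[bad]
        raise EstimationError(f"design matrix is rank deficient near column {label!r}")
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    params = pd.Series(res.params, index=["const"] + list(names))
    phat = np.asarray(res.fittedvalues)
    # separation: a diverging standardized coefficient together with fitted
    # probabilities pinned at 0/1 (large but finite coefficients on oddly
    # scaled transforms are legitimate)
    sds = X.std(axis=0, ddof=1) if X.size else np.array([])
    std_beta = np.abs(params.values[1:]) * np.where(sds > 0, sds, 1.0)
    degenerate = phat.min() < 1e-10 or phat.max() > 1 - 1e-10
    if degenerate and np.any(std_beta > 20):
        bad = list(names)[int(np.argmax(std_beta))]
        raise EstimationError(
            f"apparent separation: coefficient of {bad!r} diverged during the fit"
        )
    return params, phat, -2.0 * res.llf, res.converged


def fit_ps(
    cohort: CohortTable,
    covariates: Sequence[str],
    references=None,
    fp_age: bool = False,
    fp_alpha: float = 0.05,
) -> PSFit:
    """Estimate the propensity score by logistic regression.

    With ``fp_age=True`` and ``age`` among the covariates, the functional
    form of age is chosen by :func:`select_fractional_polynomial` and the
    selected transform replaces the linear age column.
    """
    y = cohort.df[EXPOSURE].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError("both exposure groups must be non-empty")

    design = encode_design(cohort, covariates, references)
    X, names = design.matrix, list(design.columns)
    age_powers = None
    fp_table = None

    if fp_age and AGE in names:
        other = [c for c in names if c != AGE]
        idx = [names.index(c) for c in other]
        age = cohort.df[AGE].to_numpy(dtype=float)
        age_powers, fp_table = select_fractional_polynomial(
            age, y, X[:, idx] if idx else None, alpha=fp_alpha, fixed_names=other
        )
        terms, term_names = fp_design(age, age_powers)
        X = np.column_stack([X[:, idx], terms]) if terms.size else X[:, idx]
        names = other + term_names

    max_r = np.nan
    if X.shape[1] >= 2:
        r = np.corrcoef(X, rowvar=False)
        max_r = float(np.max(np.abs(r - np.eye(len(r)))))

    params, phat, _, converged = _fit_logistic(X, names, y)
    return PSFit(
        coefficients=params,
        propensity=phat,
        exposure=y.astype(int),
        age_powers=age_powers,
        converged=bool(converged),
        max_abs_correlation=max_r,
        fp_deviance_table=fp_table,
    )


# --------------------------------------------------------------------------
# fractional polynomials (Royston–Altman closed test)
# --------------------------------------------------------------------------


def _fp_scale(x: np.ndarray) -> float:
    """Pre-scaling factor: the order of magnitude of the sample mean."""
    return 10.0 ** np.floor(np.log10(np.mean(x)))


def fp_design(x: np.ndarray, powers: tuple | None) -> tuple[np.ndarray, list]:
    """Transformed columns for a fractional-polynomial power tuple.

    Power 0 is log; a repeated power (p, p) uses the log-multiplied
    convention (x^p, x^p·log x). ``None`` or ``()`` yields no columns; the
    variable must be strictly positive (apply a shift beforehand otherwise).
    """
    if powers is None or len(powers) == 0:
        return np.empty((len(x), 0)), []
    if np.any(x <= 0):
        raise ValueError("fractional polynomials require a strictly positive variable")
    xs = x / _fp_scale(x)

    def t(p):
        return np.log(xs) if p == 0 else xs**p

    cols, names = [], []
    if len(powers) == 2 and powers[0] == powers[1]:
        p = powers[0]
        cols = [t(p), t(p) * np.log(xs)]
        names = [f"age^{p}", f"age^{p}*log(age)"]
    else:
        for p in powers:
            cols.append(t(p))
            names.append("log(age)" if p == 0 else f"age^{p}")
    return np.column_stack(cols), names


def select_fractional_polynomial(
    x: np.ndarray,
    y: np.ndarray,
    fixed: np.ndarray | None = None,
    alpha: float = 0.05,
    fixed_names: Sequence[str] | None = None,
) -> tuple[tuple, pd.DataFrame]:
    """Choose the FP form of a positive covariate by the closed deviance test.

    Fits all FP1 (8) and FP2 (36) models alongside the null and linear
    models, then tests, at level ``alpha``: (1) best FP2 vs null on 4 df —
    if not significant the variable is dropped (empty tuple); (2) best FP2
    vs linear on 3 df — if not significant, linear ``(1,)`` is kept; (3)
    best FP2 vs best FP1 on 2 df — FP1's power or the FP2 pair accordingly.

    Returns (selected powers, deviance table).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise EstimationError("degenerate input: covariate is constant")
    if np.any(x <= 0):
        x = x - x.min() + 1.0  # shift rule

    if fixed is not None and fixed.size == 0:
        fixed = None
    fixed_names = list(fixed_names) if fixed_names else (
        [f"z{i}" for i in range(fixed.shape[1])] if fixed is not None else []
    )

    def deviance(powers):
        cols, names = fp_design(x, powers)
        X = cols if fixed is None else np.column_stack([fixed, cols])
        names = fixed_names + names
        if X.shape[1] == 0:
            X = np.empty((len(x), 0))
        try:
            _, _, dev, _ = _fit_logistic(X, names, y)
        except EstimationError:
            return np.inf  # degenerate candidate transform; exclude
        return dev

    rows = [("null", (), deviance(())), ("linear", (1.0,), deviance((1.0,)))]
    fp1 = {(p,): deviance((p,)) for p in FP_POWERS}
    best1 = min(fp1, key=fp1.get)
    fp2 = {
        (p1, p2): deviance((p1, p2))
        for p1, p2 in itertools.combinations_with_replacement(FP_POWERS, 2)
    }
    best2 = min(fp2, key=fp2.get)
    rows += [(f"FP1{k}", k, v) for k, v in fp1.items()]
    rows += [(f"FP2{k}", k, v) for k, v in fp2.items()]
    table = pd.DataFrame(rows, columns=["model", "powers", "deviance"])

    d_null, d_lin = rows[0][2], rows[1][2]
    d1, d2 = fp1[best1], fp2[best2]
    crit = lambda df: stats.chi2.ppf(1 - alpha, df)
    if d_null - d2 < crit(4):
        selected = ()
    elif d_lin - d2 < crit(3):
        selected = (1.0,)
    elif d1 - d2 < crit(2):
        selected = best1
    else:
        selected = best2
    return selected, table


# --------------------------------------------------------------------------
# diagnostics and weights
# --------------------------------------------------------------------------


def check_overlap(
    psfit: PSFit, bins: int = 20, outside_threshold: float = 0.01
) -> OverlapReport:
    """Histogram comparison of p̂ between groups on shared equal-width bins.

    Bins span [0, max p̂]. The report also gives, for each group, the
    fraction of subjects falling outside the other group's [min, max] p̂
    range; overlap is flagged adequate when both fractions are below
    ``outside_threshold``.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p = psfit.propensity
    e = psfit.exposure.astype(bool)
    edges = np.linspace(0.0, p.max(), bins + 1)
    ce, _ = np.histogram(p[e], bins=edges)
    cu, _ = np.histogram(p[~e], bins=edges)
    re = (p[e].min(), p[e].max())
    ru = (p[~e].min(), p[~e].max())
    fe = float(np.mean((p[e] < ru[0]) | (p[e] > ru[1])))
    fu = float(np.mean((p[~e] < re[0]) | (p[~e] > re[1])))
    return OverlapReport(
        bin_edges=edges,
        counts_exposed=ce,
        counts_unexposed=cu,
        range_exposed=re,
        range_unexposed=ru,
        frac_exposed_outside=fe,
        frac_unexposed_outside=fu,
        adequate=(fe < outside_threshold) and (fu < outside_threshold),
    )


def check_collinearity(design: DesignMatrix, threshold: float = 0.3):
    """Pairwise Pearson correlations among predictors.

    Returns (max absolute off-diagonal correlation, correlation DataFrame,
    flag). The flag is raised when any |r| ≥ ``threshold`` (the conventional
    0.3 screen for collinearity in an exposure model).
    """
    X = design.matrix
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = design.columns[int(np.argmin(sds))]
        raise EstimationError(f"zero-variance column {bad!r}")
    r = design.correlation_matrix()
    off = np.abs(r.values - np.eye(len(r)))
    max_r = float(off.max())
    return max_r, r, max_r >= threshold


def compute_iptw(psfit: PSFit) -> IPTWeights:
    """Unstabilized ATE weights from a fitted propensity score."""
    p = np.asarray(psfit.propensity, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    e = psfit.exposure.astype(bool)
    w = np.where(e, 1.0 / p, 1.0 / (1.0 - p))
    return IPTWeights(weights=w)
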