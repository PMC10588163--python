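"""Exposure effects on latent risk classes: weighted multinomial logistic
regression with sandwich or bootstrap inference.

The outcome model is a multinomial logit of the (modally assigned) risk
class on exposure, with the no-syndrome class as reference; exponentiated
exposure coefficients are the odds ratios of each at-risk class versus the
reference. Three inference routes correspond to the three analysis datasets:

* ``unadjusted`` — unweighted fit on the original data, model-based Wald CI;
* ``iptw_robust`` — IPTW-weighted fit, HC0 sandwich CI (bread = inverse of
  the weighted information, meat = Σ w_i² s_i s_iᵀ of per-subject scores),
  which treats the estimated weights as fixed;
* ``matched_bootstrap`` — unweighted fit on the matched data; the 95% CI is
  the 2.5th/97.5th percentile of the odds ratios over B resamples of matched
  *pairs*, refitting the latent class model (at the full-sample class count)
  in each replicate, with classes re-labelled by the risk rule so that odds
  ratios are tracked by label rather than by index.

The weighted multinomial MLE and its sandwich variance are implemented
directly (Newton–Raphson on the stacked score); no off-the-shelf routine
exposes analytic weights together with the weighted sandwich needed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EXPOSURE, PAIR_ID, CohortTable, ITEM_COLUMNS
from .errors import EstimationError
from .lca import LCAModel, assign_modal, fit_lca

Z975 = stats.norm.ppf(0.975)


@dataclass
class MultinomialFit:
    """Weighted multinomial-logit fit of class on exposure."""

    classes: list  # labels; first entry is the reference
    coef: np.ndarray  # k × (C−1), rows: (const, exposure)
    cov_model: np.ndarray  # inverse weighted information
    cov_robust: np.ndarray  # HC0 sandwich
    converged: bool
    n: int

    def odds_ratios(self) -> pd.Series:
        return pd.Series(np.exp(self.coef[1]), index=self.classes[1:], name="OR")


def _multinomial_newton(X, Yind, w, max_iter=100, tol=1e-10):
    n, k = X.shape
    m = Yind.shape[1]  # non-reference classes
    B = np.zeros((k, m))
    for _ in range(max_iter):
        eta = X @ B
        eta = np.clip(eta, -500, 500)
        ex = np.exp(eta)
        denom = 1.0 + ex.sum(axis=1)
        P = ex / denom[:, None]
        G = X.T @ (w[:, None] * (Yind - P))  # k × m
        H = np.zeros((k * m, k * m))
        for c in range(m):
            for d in range(m):
                wcd = w * (P[:, c] * ((c == d) - P[:, d]))
                H[c * k : (c + 1) * k, d * k : (d + 1) * k] = -X.T @ (wcd[:, None] * X)
        g = G.T.reshape(-1)  # class-major
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular information matrix") from exc
        B = B + step.reshape(m, k).T
        if np.max(np.abs(step)) < tol:
            break
    converged = np.max(np.abs(step)) < 1e-6
    if np.max(np.abs(B)) > 20:
        converged = False  # separation flag
    eta = np.clip(X @ B, -500, 500)
    ex = np.exp(eta)
    P = ex / (1.0 + ex.sum(axis=1))[:, None]
    return B, P, H, converged


def fit_multinomial(
    classes,
    exposure,
    weights=None,
    reference: str | None = None,
) -> MultinomialFit:
    """Weighted multinomial logistic regression of class label on exposure.

    ``classes`` is a sequence of labels; ``reference`` (default: the first
    label in sorted order, or ``"no_mets"`` when present) must be non-empty,
    as must every other class.
    """
    y = pd.Series(list(classes))
    x = np.asarray(exposure, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    labels = sorted(y.unique())
    if reference is None:
        # default to the least-severe risk label present, else lexical first
        from .lca import RISK_LABELS

        ranked = [l for l in RISK_LABELS if l in labels]
        reference = ranked[0] if ranked else labels[0]
    if reference not in labels:
        raise EstimationError(f"reference class {reference!r} is empty or absent")
    ordered = [reference] + [l for l in labels if l != reference]
    counts = y.value_counts()
    empty = [l for l in ordered if counts.get(l, 0) == 0]
    if empty:
        raise EstimationError(
            f"empty class(es) {empty}: merge sparse classes before fitting"
        )

    X = np.column_stack([np.ones(n), x])
    Yind = np.column_stack([(y == l).to_numpy(dtype=float) for l in ordered[1:]])
    B, P, H, converged = _multinomial_newton(X, Yind, w)

    info = -H  # weighted observed information
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular information matrix") from exc
    # per-subject unit-weight scores, class-major stacking
    S = (Yind - P)[:, :, None] * X[:, None, :]  # n × m × k
    S = S.reshape(n, -1)
    meat = (S * (w**2)[:, None]).T @ S
    cov_robust = bread @ meat @ bread
    return MultinomialFit(
        classes=ordered,
        coef=B,
        cov_model=bread,
        cov_robust=cov_robust,
        converged=converged,
        n=n,
    )


def _exposure_ci(fit: MultinomialFit, cov: np.ndarray, method: str) -> pd.DataFrame:
    k = fit.coef.shape[0]
    rows = []
    for c, label in enumerate(fit.classes[1:]):
        b = fit.coef[1, c]
        se = np.sqrt(cov[c * k + 1, c * k + 1])
        rows.append(
            {
                "class": label,
                "OR": np.exp(b),
                "ci_low": np.exp(b - Z975 * se),
                "ci_high": np.exp(b + Z975 * se),
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def wald_ci(fit: MultinomialFit, method: str = "unadjusted") -> pd.DataFrame:
    """Model-based Wald 95% CIs on the odds-ratio scale."""
    return _exposure_ci(fit, fit.cov_model, method)


def robust_ci(fit: MultinomialFit, method: str = "iptw_robust") -> pd.DataFrame:
    """HC0 sandwich Wald 95% CIs on the odds-ratio scale."""
    return _exposure_ci(fit, fit.cov_robust, method)


@dataclass
class BootstrapResult:
    table: pd.DataFrame  # class, OR (full sample), ci_low, ci_high, method
    replicates: pd.DataFrame  # B_eff × labels matrix of replicate ORs
    n_dropped: int
    n_requested: int


def _class_or_statistic(df: pd.DataFrame, model_spec: dict):
    """Full classify-then-regress pipeline on one (re)sample.

    Fits the LCA at a fixed class count, labels classes by the risk rule,
    modally assigns subjects, and returns exposure odds ratios keyed by risk
    label. Returns None when the labelled classes are not unique or a class
    is empty (the replicate is then dropped and counted).
    """
    items = df[list(ITEM_COLUMNS)].to_numpy()
    model = fit_lca(
        items,
        n_classes=model_spec["n_classes"],
        n_starts=model_spec.get("n_starts", 5),
        seed=model_spec.get("seed", 0),
        tol=model_spec.get("tol", 1e-8),
    )
    if len(set(model.risk_labels)) != model.n_classes:
        return None
    assign = assign_modal(model, items)
    labels = pd.Series([model.risk_labels[c] for c in assign.modal])
    try:
        fit = fit_multinomial(labels, df[EXPOSURE].to_numpy(), reference="no_mets")
    except EstimationError:
        return None
    return dict(zip(fit.classes[1:], np.exp(fit.coef[1])))


def bootstrap_ci(
    matched: CohortTable,
    n_classes: int,
    B: int = 1000,
    seed: int = 0,
    lca_starts: int = 5,
    refit_lca: bool = True,
    full_model: LCAModel | None = None,
) -> BootstrapResult:
    """Pair-resampling percentile bootstrap for the matched (ATT) analysis.

    Matched pairs — not individual subjects — are resampled with
    replacement, preserving the matched design; matching itself is not
    redone. In each replicate the latent class model is refit at the fixed
    full-sample class count (``refit_lca=False`` reuses the full-sample
    parameters and only re-assigns classes), classes are re-labelled by the
    risk rule, and odds ratios are tracked by label. Replicates with an
    empty or non-uniquely-labelled class are dropped and counted; more than
    5% drops raises a warning.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    df = matched.df
    if PAIR_ID not in df.columns:
        raise ValueError("matched cohort must carry a pair_id column")

    spec = {"n_classes": n_classes, "n_starts": lca_starts}
    full = _class_or_statistic(df, {**spec, "seed": seed})
    if full is None:
        raise EstimationError("full-sample matched analysis failed")
    labels = sorted(full.keys())

    pair_groups = {k: v for k, v in df.groupby(PAIR_ID)}
    pair_ids = np.array(sorted(pair_groups.keys()))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    reps, dropped = [], 0
    for b in range(B):
        take = rng.choice(pair_ids, size=len(pair_ids), replace=True)
        rdf = pd.concat([pair_groups[k] for k in take], ignore_index=True)
        if refit_lca:
            res = _class_or_statistic(rdf, {**spec, "seed": seed + b + 1})
        else:
            res = _assign_only_statistic(rdf, full_model)
        if res is None or any(l not in res for l in labels):
            dropped += 1
            continue
        reps.append([res[l] for l in labels])
    if dropped > 0.05 * B:
        warnings.warn(
            f"{dropped}/{B} bootstrap replicates dropped (empty/degenerate class)"
        )
    if not reps:
        raise EstimationError("all bootstrap replicates failed")
    rep = pd.DataFrame(reps, columns=labels)
    rows = []
    for l in labels:
        lo, hi = np.percentile(rep[l].to_numpy(), [2.5, 97.5])
        rows.append(
            {
                "class": l,
                "OR": full[l],
                "ci_low": lo,
                "ci_high": hi,
                "method": "matched_bootstrap",
            }
        )
    return BootstrapResult(
        table=pd.DataFrame(rows), replicates=rep, n_dropped=dropped, n_requested=B
    )


def _assign_only_statistic(df: pd.DataFrame, model: LCAModel | None):
    if model is None:
        raise ValueError("full_model is required when refit_lca=False")
    items = df[list(ITEM_COLUMNS)].to_numpy()
    assign = assign_modal(model, items)
    labels = pd.Series([model.risk_labels[c] for c in assign.modal])
    try:
        fit = fit_multinomial(labels, df[EXPOSURE].to_numpy(), reference="no_mets")
    except EstimationError:
        return None
    return dict(zip(fit.classes[1:], np.exp(fit.coef[1])))
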