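"""Weighted latent class analysis of binary indicators by EM.

The measurement model is a finite mixture: each subject belongs to one of C
latent classes with prevalences γ (Σγ = 1), and given class c the J binary
indicators are independent Bernoulli with item-response probabilities ρ_cj.
The weighted log-likelihood maximized here is

    LL = Σ_i w_i · log Σ_c γ_c Π_j ρ_cj^{y_ij} (1 − ρ_cj)^{1−y_ij},

with w_i the analysis weights (IPTW weights, or 1). Estimation is EM on the
collapsed 2^J response patterns (so cost is independent of n), with multiple
seeded random starts; the E-step posteriors are the usual Bayes weights and
the M-step updates are weighted-count ratios, with ρ clamped away from 0/1.

Model selection across class counts uses the standard penalized indices

    AIC  = −2LL + 2p            BIC  = −2LL + p·ln n
    CAIC = −2LL + p(ln n + 1)   ABIC = −2LL + p·ln((n+2)/24)

with p = (C−1) + C·J free parameters and n the number of observations (rows,
not the sum of weights). Classes are labelled by how many indicators exceed
a 0.5 response probability — none → no syndrome, one → low risk, two →
moderate, three or more → high risk — and canonically ordered by that
severity (ties by descending prevalence), which also neutralizes label
switching across random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError

RHO_EPS = 1e-6
RISK_LABELS = ("no_mets", "low", "moderate", "high")


def risk_label(rho_row: np.ndarray) -> str:
    """Label one class from its item-response probabilities (> 0.5 rule)."""
    k = int(np.sum(np.asarray(rho_row) > 0.5))
    return RISK_LABELS[min(k, 3)]


def label_classes(rho: np.ndarray) -> list:
    """Risk label per class (rows of ρ)."""
    return [risk_label(row) for row in np.atleast_2d(rho)]


def fit_indices(ll: float, p: int, n: int) -> dict:
    """AIC/BIC/CAIC/ABIC from a log-likelihood, parameter count and n."""
    if n < 1 or p < 0:
        raise ValueError("need n >= 1 and p >= 0")
    m2ll = -2.0 * ll
    return {
        "AIC": m2ll + 2.0 * p,
        "BIC": m2ll + p * np.log(n),
        "CAIC": m2ll + p * (np.log(n) + 1.0),
        "ABIC": m2ll + p * np.log((n + 2.0) / 24.0),
    }


@dataclass
class LCAModel:
    """A fitted latent class model."""

    n_classes: int
    gamma: np.ndarray  # class prevalences, sum to 1
    rho: np.ndarray  # C × J item-response probabilities
    log_likelihood: float
    n: int  # observation rows used for the indices
    n_parameters: int
    indices: dict
    risk_labels: list
    converged: bool
    n_starts: int
    best_start: int
    n_iterations: int = 0
    ll_trace: list = field(default_factory=list)  # winning start's LL path

    @property
    def severity_order(self):
        return [RISK_LABELS.index(l) for l in self.risk_labels]


@dataclass
class ClassAssignment:
    """Posterior membership probabilities and modal class per subject."""

    posterior: np.ndarray  # n × C, rows sum to 1
    modal: np.ndarray  # 0-based class index (canonical order)


def _collapse(items: np.ndarray, weights: np.ndarray):
    """Unique response patterns and their total weight."""
    patterns, inverse = np.unique(items, axis=0, return_inverse=True)
    w = np.zeros(len(patterns))
    np.add.at(w, inverse, weights)
    return patterns, w, inverse


def _pattern_loglik(patterns: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """m × C matrix of log f_c(pattern) under class-conditional independence."""
    lr, lc = np.log(rho), np.log1p(-rho)
    return patterns @ lr.T + (1 - patterns) @ lc.T


def _posterior(patterns, gamma, rho):
    a = _pattern_loglik(patterns, rho) + np.log(gamma)
    amax = a.max(axis=1, keepdims=True)
    lse = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
    tau = np.exp(a - lse[:, None])
    return tau, lse


def _em(patterns, w, gamma, rho, tol, max_iter, monotone_slack=1e-9):
    ll_old = -np.inf
    converged = False
    it = 0
    trace = []
    for it in range(1, max_iter + 1):
        tau, lse = _posterior(patterns, gamma, rho)
        ll = float(w @ lse)
        trace.append(ll)
        if ll < ll_old - monotone_slack * max(1.0, abs(ll_old)):
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        if np.isfinite(ll_old) and (ll - ll_old) <= tol * abs(ll_old):
            converged = True
            break
        ll_old = ll
        wt = w[:, None] * tau
        colw = wt.sum(axis=0)
        gamma = colw / colw.sum()
        rho = (wt.T @ patterns) / np.maximum(colw[:, None], 1e-300)
        rho = np.clip(rho, RHO_EPS, 1 - RHO_EPS)
    tau, lse = _posterior(patterns, gamma, rho)
    ll = float(w @ lse)
    trace.append(ll)
    return gamma, rho, ll, converged, it, trace


def _canonicalize(gamma, rho):
    """Order classes by risk severity, ties by descending prevalence."""
    labels = label_classes(rho)
    sev = np.array([RISK_LABELS.index(l) for l in labels])
    order = np.lexsort((-gamma, sev))
    return gamma[order], rho[order], [labels[i] for i in order], order


def fit_lca(
    items: np.ndarray,
    weights: np.ndarray | None = None,
    n_classes: int = 3,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int = 0,
) -> LCAModel:
    """Fit a C-class weighted latent class model, best of ``n_starts`` starts.

    ``items`` is an n × J 0/1 array; ``weights`` positive per-subject
    analysis weights (unit weights when omitted). Start c initializes ρ
    uniform on (0.2, 0.8) and γ from a flat simplex draw, all derived from
    ``seed``; the run is fully deterministic.
    """
    items = np.asarray(items)
    if items.ndim != 2:
        raise ValueError("items must be a 2-D array")
    if not np.isin(items, (0, 1)).all():
        raise EstimationError("items must be binary 0/1")
    n, J = items.shape
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")

    patterns, pw, _ = _collapse(items.astype(float), w)
    C = n_classes

    if C == 1:
        # closed form: independent Bernoulli at the weighted item means
        rho = np.clip((w @ items) / w.sum(), RHO_EPS, 1 - RHO_EPS)[None, :]
        gamma = np.array([1.0])
        _, lse = _posterior(patterns, gamma, rho)
        ll = float(pw @ lse)
        best = (gamma, rho, ll, True, 0, 0, [ll])
    else:
        rng_master = np.random.SeedSequence(seed).spawn(n_starts)
        best = None
        for s, ss in enumerate(rng_master):
            rng = np.random.default_rng(ss)
            rho0 = rng.uniform(0.2, 0.8, size=(C, J))
            gamma0 = rng.dirichlet(np.ones(C))
            gamma_s, rho_s, ll_s, conv_s, it_s, trace_s = _em(
                patterns, pw, gamma0, rho0, tol, max_iter
            )
            if best is None or ll_s > best[2]:
                best = (gamma_s, rho_s, ll_s, conv_s, it_s, s, trace_s)

    gamma, rho, ll, converged, iters, best_start, trace = best
    gamma, rho, labels, _ = _canonicalize(gamma, rho)
    p = (C - 1) + C * J
    return LCAModel(
        n_classes=C,
        gamma=gamma,
        rho=rho,
        log_likelihood=ll,
        n=n,
        n_parameters=p,
        indices=fit_indices(ll, p, n),
        risk_labels=labels,
        converged=bool(converged),
        n_starts=n_starts if C > 1 else 1,
        best_start=best_start,
        n_iterations=iters,
        ll_trace=trace,
    )


def sweep_classes(
    items: np.ndarray,
    weights: np.ndarray | None = None,
    max_classes: int = 6,
    criterion: str = "BIC",
    **fit_kwargs,
) -> tuple[pd.DataFrame, int, dict]:
    """Fit 1..max_classes models and recommend a class count.

    The recommendation is the argmin of ``criterion`` (BIC by default); the
    returned dict reports whether CAIC and ABIC agree with it, mirroring the
    consensus reading of an index table.
    """
    rows, models = [], {}
    for C in range(1, max_classes + 1):
        m = fit_lca(items, weights=weights, n_classes=C, **fit_kwargs)
        models[C] = m
        rows.append(
            {
                "n_classes": C,
                "log_likelihood": m.log_likelihood,
                "n_parameters": m.n_parameters,
                **m.indices,
                "converged": m.converged,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table[criterion].idxmin(), "n_classes"])
    agreement = {
        ix: int(table.loc[table[ix].idxmin(), "n_classes"]) == best
        for ix in ("CAIC", "ABIC", "AIC")
    }
    return table, best, {"criterion": criterion, "agreement": agreement,
                         "models": models}


def assign_modal(
    model: LCAModel, items: np.ndarray, weights: np.ndarray | None = None
) -> ClassAssignment:
    """Posterior class probabilities and modal assignment per subject.

    Posteriors follow Bayes' rule from the fitted (γ, ρ); the modal class is
    the argmax, with exact ties going to the lower canonical class index.
    """
    items = np.asarray(items, dtype=float)
    tau, _ = _posterior(items, model.gamma, model.rho)
    return ClassAssignment(posterior=tau, modal=np.argmax(tau, axis=1))
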