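"""End-to-end orchestration of the four-step causal latent-class analysis.

Given one configuration (input cohort or generator scenario, covariates,
caliper, class-sweep settings, bootstrap size, master seed), the pipeline

1. fits the propensity model and checks overlap/collinearity,
2. computes ATE inverse-probability weights and the caliper-matched set,
3. tabulates standardized differences in original/weighted/matched data,
4. sweeps latent class models per analysis dataset, labels the chosen model,
   modally assigns subjects, and estimates per-class exposure odds ratios
   (unadjusted Wald, IPTW sandwich, matched pair-bootstrap).

Every artifact is written as CSV (models as YAML) into the output directory
with a manifest of content hashes; reruns under the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .balance import balance_table
from .cohort import (
    AGE,
    CONFOUNDERS,
    EXPOSURE,
    ITEM_COLUMNS,
    CohortTable,
    encode_design,
    read_cohort,
)
from .effects import bootstrap_ci, fit_multinomial, robust_ci, wald_ci
from .lca import assign_modal, fit_lca, sweep_classes
from .matching import match_nearest, matched_cohort
from .propensity import check_collinearity, check_overlap, compute_iptw, fit_ps


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full run."""

    input_path: str | None = None  # CSV cohort; None → simulate
    scenario: str = "tlgs_like"  # generator scenario when simulating
    n: int = 4857
    confounded: bool = False
    covariates: tuple = CONFOUNDERS
    fp_age: bool = False
    caliper: float = 0.05
    caliper_scale: str = "ps"
    max_classes: int = 6
    lca_starts: int = 20
    lca_tol: float = 1e-8
    bootstrap_reps: int = 1000
    seed: int = 0
    output_dir: str = "pslca_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.covariates, list):
            cfg.covariates = tuple(cfg.covariates)
        return cfg


@dataclass
class ResultsBundle:
    """Handles to the tables a full run produces."""

    baseline: pd.DataFrame
    ps_diagnostics: dict
    balance: pd.DataFrame
    sweeps: dict  # dataset -> index table
    models: dict  # dataset -> LCAModel
    effects: pd.DataFrame
    manifest: dict
    output_dir: Path


def baseline_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-exposure-group n (%) for each confounder level, mean (SD) for age."""
    df = cohort.df
    e = df[EXPOSURE] == 1
    rows = []
    schema = cohort.schema
    for cov in CONFOUNDERS:
        if cov == AGE:
            rows.append(
                {
                    "characteristic": "age",
                    "level": "mean_sd",
                    "exposed": f"{df.loc[e, AGE].mean():.2f} ({df.loc[e, AGE].std(ddof=1):.2f})",
                    "unexposed": f"{df.loc[~e, AGE].mean():.2f} ({df.loc[~e, AGE].std(ddof=1):.2f})",
                }
            )
            continue
        levels = schema.categorical_levels.get(cov, (1, 0))
        for lev in levels:
            ne = int((df.loc[e, cov] == lev).sum())
            nu = int((df.loc[~e, cov] == lev).sum())
            rows.append(
                {
                    "characteristic": cov,
                    "level": str(lev),
                    "exposed": f"{ne} ({100 * ne / max(e.sum(), 1):.1f})",
                    "unexposed": f"{nu} ({100 * nu / max((~e).sum(), 1):.1f})",
                    "n_exposed": ne,
                    "n_unexposed": nu,
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _model_dict(model) -> dict:
    return {
        "n_classes": model.n_classes,
        "gamma": [float(g) for g in model.gamma],
        "rho": [[float(r) for r in row] for row in model.rho],
        "risk_labels": list(model.risk_labels),
        "log_likelihood": float(model.log_likelihood),
        "indices": {k: float(v) for k, v in model.indices.items()},
        "n": int(model.n),
        "converged": bool(model.converged),
    }


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage, **kw):
        log_lines.append(
            f"{stage}: " + " ".join(f"{k}={v}" for k, v in kw.items())
        )

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    written: list[Path] = []

    def write_csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    # ---- input ----
    if config.input_path:
        cohort = read_cohort(config.input_path, stage="lca")
        truth = None
    else:
        spec = simulate.tlgs_like(
            n=config.n,
            seed=int(seeds[0].generate_state(1)[0] % (2**31)),
            confounded=config.confounded,
        )
        cohort, truth = simulate.simulate_cohort(spec)
        write_csv(cohort.df, "cohort.csv")
        write_csv(truth.frame(), "truth.csv")
    log("input", n=len(cohort), simulated=config.input_path is None,
        seed=config.seed)

    # ---- step 1: propensity model + diagnostics ----
    psfit = fit_ps(cohort, config.covariates, fp_age=config.fp_age)
    design = encode_design(cohort, config.covariates)
    max_r, _, collinear = check_collinearity(design)
    overlap = check_overlap(psfit)
    diagnostics = {
        "converged": psfit.converged,
        "age_powers": psfit.age_powers,
        "max_abs_correlation": max_r,
        "collinearity_flag": collinear,
        "overlap_adequate": overlap.adequate,
        "frac_exposed_outside": overlap.frac_exposed_outside,
        "frac_unexposed_outside": overlap.frac_unexposed_outside,
    }
    log("propensity", **diagnostics)

    # ---- step 2: weights and matching ----
    iptw = compute_iptw(psfit)
    ps_df = pd.DataFrame(
        {
            "subject_id": cohort.df["subject_id"],
            "propensity": psfit.propensity,
            "iptw": iptw.weights,
        }
    )
    write_csv(ps_df, "ps.csv")
    hist = pd.DataFrame(
        {
            "bin_low": overlap.bin_edges[:-1],
            "bin_high": overlap.bin_edges[1:],
            "count_exposed": overlap.counts_exposed,
            "count_unexposed": overlap.counts_unexposed,
        }
    )
    write_csv(hist, "ps_histogram.csv")

    matched_set = match_nearest(
        psfit.propensity,
        psfit.exposure,
        subject_ids=cohort.df["subject_id"].to_numpy(),
        caliper=config.caliper,
        scale=config.caliper_scale,
    )
    mcohort = matched_cohort(matched_set, cohort)
    write_csv(matched_set.pairs, "pairs.csv")
    write_csv(mcohort.df, "matched.csv")
    log("matching", n_pairs=matched_set.n_matched,
        n_unmatched=len(matched_set.unmatched_exposed))

    # ---- step 3: balance ----
    bal = balance_table(
        cohort, config.covariates, weights=iptw.weights, matched=mcohort
    )
    write_csv(bal.rounded(), "balance.csv")
    log("balance", max_weighted=float(bal.table["d_weighted"].max()),
        max_matched=float(bal.table["d_matched"].max()))

    # ---- step 4: latent classes + effects per dataset ----
    datasets = {
        "original": (cohort, None),
        "weighted": (cohort, iptw.weights),
        "matched": (mcohort, None),
    }
    sweeps, models, effect_frames = {}, {}, []
    lca_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    for name, (data, w) in datasets.items():
        items = data.df[list(ITEM_COLUMNS)].to_numpy()
        table, best_c, _ = sweep_classes(
            items,
            weights=w,
            max_classes=config.max_classes,
            n_starts=config.lca_starts,
            tol=config.lca_tol,
            seed=lca_seed,
        )
        sweeps[name] = table
        write_csv(table, f"lca_sweep_{name}.csv")
        model = fit_lca(
            items,
            weights=w,
            n_classes=best_c,
            n_starts=config.lca_starts,
            tol=config.lca_tol,
            seed=lca_seed,
        )
        models[name] = model
        mpath = out / f"lca_model_{name}.yaml"
        mpath.write_text(yaml.safe_dump(_model_dict(model), sort_keys=False))
        written.append(mpath)
        assign = assign_modal(model, items)
        post = pd.DataFrame(
            assign.posterior,
            columns=[f"posterior_{l}_{i}" for i, l in enumerate(model.risk_labels)],
        )
        post.insert(0, "subject_id", data.df["subject_id"].to_numpy())
        post["modal_label"] = [model.risk_labels[c] for c in assign.modal]
        write_csv(post, f"lca_posterior_{name}.csv")
        log(f"lca_{name}", best_c=best_c, ll=round(model.log_likelihood, 3))

        labels = pd.Series([model.risk_labels[c] for c in assign.modal])
        exposure = data.df[EXPOSURE].to_numpy()
        if name == "original":
            fit = fit_multinomial(labels, exposure, reference="no_mets")
            effect_frames.append(wald_ci(fit, method="unadjusted"))
        elif name == "weighted":
            fit = fit_multinomial(labels, exposure, weights=w, reference="no_mets")
            effect_frames.append(robust_ci(fit, method="iptw_robust"))
        else:
            boot = bootstrap_ci(
                data,
                n_classes=best_c,
                B=config.bootstrap_reps,
                seed=int(seeds[2].generate_state(1)[0] % (2**31)),
                lca_starts=max(5, config.lca_starts // 4),
            )
            effect_frames.append(boot.table)
            log("bootstrap", dropped=boot.n_dropped, requested=boot.n_requested)

    effects = pd.concat(effect_frames, ignore_index=True)
    write_csv(effects, "effects.csv")

    baseline = baseline_table(cohort)
    write_csv(baseline, "baseline.csv")

    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    written.append(log_path)
    manifest = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return ResultsBundle(
        baseline=baseline,
        ps_diagnostics=diagnostics,
        balance=bal.table,
        sweeps=sweeps,
        models=models,
        effects=effects,
        manifest=manifest,
        output_dir=out,
    )
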