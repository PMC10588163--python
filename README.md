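# pslca — propensity-score causal analysis of latent metabolic-syndrome classes

`pslca` implements a causal-inference pipeline for epidemiologists studying
how a binary exposure (daily smoking) shifts people between *latent classes*
of metabolic syndrome, rather than treating the syndrome as an all-or-none
diagnosis. It combines two standard tools:

* **propensity-score confounding adjustment** — a logistic exposure model
  `PS = P(smoking = 1 | confounders)` (gender, age with optional
  fractional-polynomial terms, marital status, education, occupation,
  physical activity), used either for inverse-probability-of-treatment
  weighting (IPTW; ATE weights `1/PS` for the exposed and `1/(1−PS)` for the
  unexposed) or for 1:1 nearest-neighbour matching without replacement under
  a ±0.05 caliper (ATT);
* **weighted latent class analysis** — a finite mixture of five binary
  indicators (abdominal obesity, impaired fasting glucose,
  hypertriglyceridemia, hypertension, low HDL) with class prevalences γ and
  item-response probabilities ρ, estimated by EM on the weighted likelihood

      LL = Σᵢ wᵢ log Σ_c γ_c Π_j ρ_cj^{y_ij} (1−ρ_cj)^{1−y_ij},

  classes labelled by how many indicators exceed ρ = 0.5 (none / low /
  moderate / high risk), the class count chosen by AIC/BIC/CAIC/ABIC over a
  1–6 sweep.

Exposure effects on the latent risk classes are estimated by multinomial
logistic regression (no-syndrome class as reference): model-based Wald
intervals for the unadjusted analysis, HC0 sandwich intervals for IPTW, and
a pair-resampling percentile bootstrap (B = 1000) for the matched analysis.
Covariate balance before/after adjustment is checked with standardized
differences at the conventional 0.1 threshold.

Because the motivating cohort (the Tehran Lipid and Glucose Study) is not
publicly deposited, the package ships a synthetic-cohort generator whose
confounder distributions are calibrated to the study's published baseline
table and whose exposure, class-membership and measurement models have
recorded ground truth — so every step of the pipeline can be validated by
parameter recovery instead of data access.

## Worked example

```python
import pslca
from pslca import simulate as sim

spec = sim.tlgs_like(n=4857, seed=11, confounded=True)
cohort, truth = sim.simulate_cohort(spec)

psfit = pslca.fit_ps(cohort, ["gender", "age", "marital_status",
                              "education", "occupation", "physical_activity"])
weights = pslca.compute_iptw(psfit).weights
matched = pslca.matched_cohort(
    pslca.match_nearest(psfit.propensity, psfit.exposure,
                        subject_ids=cohort.df.subject_id.to_numpy()),
    cohort,
)
bal = pslca.balance_table(cohort, ["gender", "age", "physical_activity"],
                          weights=weights, matched=matched)
print(bal.rounded()[["confounder", "d_original", "d_weighted", "d_matched"]])
```

```
          confounder  d_original  d_weighted  d_matched
0             gender       1.245       0.018      0.000
1                age       0.060       0.077      0.037
2  physical_activity       0.114       0.081      0.020
```

Gender is severely imbalanced in the raw data (d = 1.245, matching the
magnitude seen in the motivating cohort) and balanced (d < 0.1) after both
weighting and matching. Fitting the latent class model and the effect model
on the matched data:

```python
from pslca.cohort import ITEM_COLUMNS
from pslca.lca import fit_lca, assign_modal

model = fit_lca(matched.df[list(ITEM_COLUMNS)].to_numpy(), n_classes=3, seed=0)
print(model.risk_labels, model.gamma.round(3))
boot = pslca.bootstrap_ci(matched, n_classes=3, B=200, seed=3)
print(boot.table)
```

```
['no_mets', 'low', 'moderate'] [0.178 0.425 0.397]
      class        OR    ci_low   ci_high             method
0       low  1.193074  0.864617  1.585959  matched_bootstrap
1  moderate  1.862975  1.283216  2.664152  matched_bootstrap
```

The three classes recover the generating structure (no-syndrome /
abdominal-obesity-driven low risk / lipid-driven moderate risk). The
matched cohort conditions on being exposed-like (ATT), so its class mix
differs from the population's; the bootstrap intervals for both at-risk
classes are consistent with the generating marginal effects (1.45, 1.68).

The same pipeline is available from the shell:

```bash
pslca run-all --seed 3 --out-dir results/
pslca simulate --n 4857 --seed 0 --out cohort   # or any stage separately
```

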