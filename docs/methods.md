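# Methods

## The estimation problem

Metabolic syndrome is conventionally diagnosed as "three or more of five
components" (abdominal obesity, impaired fasting glucose,
hypertriglyceridemia, hypertension, low HDL). `pslca` instead treats the
syndrome as a *latent class* variable measured by the five binary
components, and asks a causal question about a binary exposure (daily
smoking): how does exposure shift membership across the latent risk
classes, once measured confounders (gender, age, marital status, education,
occupation, physical activity) are adjusted for?

The pipeline has four steps: (1) estimate the propensity score and check
its diagnostics; (2) construct an adjusted dataset, either by inverse
probability weighting (ATE) or 1:1 caliper matching (ATT); (3) verify
covariate balance with standardized differences; (4) fit a weighted latent
class model on the adjusted data and regress the assigned risk class on
exposure with a multinomial logit.

## Propensity model

The PS is a maximum-likelihood logistic regression of exposure on the
confounder design matrix (k−1 dummy coding; reference levels default to
the modal categories: married, high school, employed). Age may enter
through fractional polynomials: the candidate set is the standard powers
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log; a repeated power p contributes
x^p and x^p·log x), with age pre-scaled by the order of magnitude of its
sample mean. Selection is the closed deviance test at α = 0.05: best FP2
vs null (4 df), vs linear (3 df), vs best FP1 (2 df). Candidate transforms
whose fit degenerates (separation) are excluded from the comparison rather
than aborting it.

Diagnostics: a shared-bin histogram of p̂ by exposure group (20 equal-width
bins on [0, max p̂]) with an "adequate overlap" flag when fewer than 1% of
each group lies outside the other group's p̂ range, and the predictor
correlation matrix with a warning at max |r| ≥ 0.3. Separation is flagged
when a standardized coefficient diverges (|β|·SD > 20) *and* fitted
probabilities are pinned at 0/1; rank deficiency is reported with the
offending column.

ATE weights are unstabilized — `1/p̂` (exposed), `1/(1−p̂)` (unexposed) —
with no truncation by default. Under the default synthetic scenario these
weights have mean ≈ 2.0 and SD ≈ 5.3, closely matching the weight
distribution reported for the motivating cohort (2.02, SD 5.57); the
exposed pseudo-population's effective sample size is correspondingly small
(≈ 180 at n = 5000), which matters for how balance is asserted (below).

## Matching

1:1 nearest-neighbour matching without replacement, caliper ±0.05 on the
probability scale. The alternative caliper 0.2·SD(logit p̂) is computable
(`caliper_from_logit_sd`, sample SD with n−1 denominator) and selectable
via `scale="logit_sd"`, but the probability-scale default reflects the
motivating analysis, which computed the logit-SD caliper (0.25), judged it
too wide, and used ±0.05. The greedy order is deterministic and documented:
exposed subjects in descending p̂ (ties by ascending id), each matched to
the closest available unexposed subject (distance ties by ascending id),
skipped when the best distance exceeds the caliper. Enlarging the caliper
can then never reduce the number of pairs.

## Balance

Standardized differences use the standard two-group formulas — difference
in means over √((s²₁+s²₀)/2) for continuous covariates, difference in
proportions over √((p₁(1−p₁)+p₀(1−p₀))/2) for binary ones — reported as
absolute values, flagged at 0.1. Weighted variants substitute weighted
means/proportions and, for the continuous case, weighted variances in the
frequency-weight convention Σw(x−x̄_w)²/(Σw−1), which reduces exactly to
the unweighted formula at unit weights. Categorical confounders are checked
level-by-level against their reference, matching the layout of published
balance tables. Levels absent from both groups yield an undefined d,
reported as NaN.

A caution on what balance assertions can promise: the PS balancing property
applies to covariates that enter the PS. For covariates unrelated to
exposure, and for ~2%-prevalence category dummies generally, the sampling
SD of d at the weighted effective sample sizes above is ≈ 0.06–0.08, so a
single draw's maximum over 15 rows crosses 0.1 regularly by chance alone.
The package's own validation therefore asserts weighted/matched balance on
the covariates that generate the exposure, and averages over replicates
where a single draw would be noise-dominated.

## Weighted latent class model

The measurement model is class-conditional independence: C classes with
prevalences γ and a C×5 matrix ρ of item-response probabilities. The
weighted log-likelihood is maximized by EM on the collapsed 2⁵ response
patterns (cost independent of n): E-step posteriors by Bayes rule, M-step
weighted-count updates, ρ clamped to [10⁻⁶, 1−10⁻⁶]. Convergence is a
relative LL change below 10⁻⁸ (cap 5000 iterations); 20 seeded random
starts by default (ρ ~ U(0.2, 0.8), γ from a flat simplex draw), keeping
the best LL. The EM trace is retained on the fitted model and the
implementation raises if the weighted LL ever decreases.

Classes are labelled by k = #{j : ρ_cj > 0.5}: none → no syndrome, one →
low risk, two → moderate, ≥3 → high risk; canonical class order is by that
severity, ties by descending γ. This both matches how published solutions
are presented and neutralizes label switching across starts and bootstrap
replicates. Modal assignment is the posterior argmax with exact ties going
to the lower canonical index.

Fit indices over a 1..6-class sweep use p = (C−1) + 5C parameters and

    AIC = −2LL + 2p                    BIC  = −2LL + p·ln n
    CAIC = −2LL + p(ln n + 1)          ABIC = −2LL + p·ln((n+2)/24)

with **n = number of rows, not the sum of weights**: the published index
table prints N = 4857 for the weighted analysis although raw ATE weights
sum to ≈ 2n, and its index spacings are consistent only with row counts.
The recommended C is the BIC argmin, with CAIC/ABIC (and AIC) agreement
reported, mirroring the consensus reading used in practice.

## Effect estimation

The outcome model is a multinomial logit of risk-class label on exposure
(reference: the no-syndrome class), fitted by Newton–Raphson on the
weighted score; this is written in-house because no available routine
combines analytic weights with the weighted HC0 sandwich
(H⁻¹ [Σ wᵢ² sᵢsᵢᵀ] H⁻¹, scores per unit weight) needed for IPTW. Three
inference routes: model-based Wald (unadjusted), sandwich Wald (IPTW;
estimated weights treated as fixed), and a percentile bootstrap for the
matched design — B = 1000 resamples of matched *pairs*, the latent class
model refit per replicate at the full-sample class count (reuse of the
full-sample measurement model is available via `refit_lca=False`),
classes re-labelled by the risk rule, odds ratios tracked by label, and the
2.5th/97.5th percentiles taken per label. Replicates with an empty or
non-uniquely-labelled class are dropped and counted (warning above 5%).
Matching is not redone inside replicates: the matched set is treated as the
sample, a standard and documented simplification.

Because the latent-class three-step route (classify, then regress) is used,
classification error attenuates effect estimates somewhat; the one-step
alternative is out of scope and the package's recovery guarantees are
stated for the measurement parameters and for effect estimation with known
classes.

## Synthetic cohort

The generator produces exactly the structure the pipeline assumes, in three
seeded stages (one master seed, per-stage children via
`SeedSequence.spawn`): confounders with categorical probabilities taken
from the motivating study's published baseline table (60.9% female, age ~
truncated normal N(39.1, 13.5²) on [20, 90], etc.); exposure ~
Bernoulli(expit(β₀ + 2.46·male + 0.012·age − 0.18·activity)) with β₀ =
−4.0534 calibrated so marginal prevalence is the published 10.5%; and a
multinomial-logit class model (base shares 0.30/0.36/0.34, the published
matched-data three-class solution) with exposure log-odds log(1.45) and
log(1.68) for the low- and moderate-risk classes, followed by
class-conditional Bernoulli items.

The default ρ keeps the qualitative pattern of the published solutions — a
class low on everything, an abdominal-obesity-driven low-risk class, a
hypertriglyceridemia + low-HDL moderate-risk class — with separation chosen
so the model is actually estimable at the default n: weakly separated
classes (as in the published original-data point estimates taken literally)
leave the MLE's sampling error above 0.05 per parameter at n = 5000, which
would make parameter-recovery validation meaningless. Entries were also
kept ≥ 0.15 away from the 0.5 labelling threshold so risk labels are stable
across bootstrap refits.

With `confounded=True`, gender (log-odds 0.8) also enters the class model,
making the crude exposure–class association biased while PS methods remain
consistent. Odds ratios are non-collapsible, so under confounding the
marginal (ATE) estimand differs from exp(coefficient);
`true_marginal_or` computes the per-cohort marginal truth by averaging
class probabilities under exposure forced to 1 and 0.

What the generator does **not** emulate: survey sampling design, attrition,
measurement error in items or confounders, unmeasured confounding (income,
alcohol) beyond the single configurable knob, and any dependence between
items within class. Passing tests therefore validate the estimators under
their stated assumptions, not robustness to their violation.

## Validation sizes and numerical choices

The shipped validation uses: recovery at n = 5000 (median aligned max-error
over 5 replicates < 0.05); BIC selection at n = 5000 (true C = 3 chosen in
≥ 80% of 20 replicates); bias reduction (50 replicates) and sandwich-CI
coverage (200 replicates, 95% ± 3 points) under the confounded generator
with known classes; matching validity and balance on a true-PS scenario.
These sizes keep the full validation around a minute on one CPU while
leaving each assertion's Monte-Carlo error well inside its band. Exact
reproduction checks (published balance table from baseline counts; index
rows from back-solved −2LL) are deterministic.

Known numerical edge cases: the EM clamp means "pure" classes sit at
ρ = 10⁻⁶/1−10⁻⁶ rather than 0/1; fit-index n must be ≥ 1; the logit-SD
caliper of a constant p̂ is 0; and the published age standardized
difference (0.184) is not reproducible from the published rounded age
summaries, which imply 0.152 — the discrepancy is recorded rather than
resolved, and age is excluded from the exact-reproduction check.
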