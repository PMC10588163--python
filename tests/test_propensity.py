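"""Propensity estimation, fractional polynomials, diagnostics, IPTW."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from pslca import simulate as sim
from pslca.balance import std_diff_binary, std_diff_continuous
from pslca.cohort import CohortTable, DEFAULT_SCHEMA, encode_design
from pslca.errors import EstimationError
from pslca.propensity import (
    PSFit,
    check_collinearity,
    check_overlap,
    compute_iptw,
    fit_ps,
    fp_design,
    select_fractional_polynomial,
)


def _cohort_with_x(x, y):
    n = len(x)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "exposure": y,
            "gender": 0,
            "age": np.asarray(x, dtype=float),
            "marital_status": "married",
            "education": "high_school",
            "occupation": "employed",
            "physical_activity": 0,
        }
    )
    return CohortTable(df=df, schema=DEFAULT_SCHEMA)


def test_intercept_only_fit_returns_prevalence():
    rng = np.random.default_rng(0)
    y = rng.binomial(1, 0.3, size=500)
    cohort = _cohort_with_x(np.ones(500) * 40, y)
    fit = fit_ps(cohort, covariates=[])
    assert np.allclose(fit.propensity, y.mean(), atol=1e-8)


def test_logistic_mle_consistency():
    """β̂ → β for a single-covariate logistic model at large n."""
    rng = np.random.default_rng(1)
    n = 50_000
    x = rng.normal(0, 1, n)
    y = rng.binomial(1, expit(-2.0 + 1.0 * x))
    fit = fit_ps(_cohort_with_x(x, y), covariates=["age"])
    assert abs(fit.coefficients["const"] - (-2.0)) < 0.08
    assert abs(fit.coefficients["age"] - 1.0) < 0.08


def test_default_scenario_recovers_exposure_model(default_cohort):
    cohort, truth, spec = default_cohort
    fit = fit_ps(cohort, covariates=["gender", "age", "physical_activity"])
    # true propensity is reproduced up to estimation error
    assert np.abs(fit.propensity - truth.true_propensity).mean() < 0.01


def test_duplicated_covariate_is_rank_deficiency_error():
    rng = np.random.default_rng(2)
    y = rng.binomial(1, 0.4, 200)
    cohort = _cohort_with_x(rng.normal(40, 5, 200), y)
    cohort.df["age2"] = cohort.df["age"]
    cohort.schema = DEFAULT_SCHEMA
    with pytest.raises(EstimationError, match="rank deficient"):
        fit_ps(cohort, covariates=["age", "age2"])


def test_empty_group_rejected():
    cohort = _cohort_with_x(np.arange(1, 11, dtype=float), np.zeros(10, dtype=int))
    with pytest.raises(EstimationError, match="non-empty"):
        fit_ps(cohort, covariates=["age"])


class TestFractionalPolynomial:
    def test_closed_test_retains_linear_under_linear_truth(self):
        """Type-I behaviour: with a genuinely linear age effect the closed
        test should keep the linear form in most replicates (~95%)."""
        rng = np.random.default_rng(3)
        kept = 0
        reps = 25
        for _ in range(reps):
            n = 3000
            age = rng.uniform(20, 80, n)
            y = rng.binomial(1, expit(-3.0 + 0.04 * age))
            powers, _ = select_fractional_polynomial(age, y)
            kept += powers == (1.0,)
        assert kept >= 0.8 * reps

    def test_detects_strong_nonlinearity(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 8
        for _ in range(reps):
            n = 4000
            age = rng.uniform(20, 80, n)
            z = (age - 50.0) / 10.0
            y = rng.binomial(1, expit(-1.5 + 0.9 * z**2))
            powers, _ = select_fractional_polynomial(age, y)
            hits += powers not in ((), (1.0,))
        assert hits > reps / 2

    def test_constant_covariate_is_degenerate(self):
        with pytest.raises(EstimationError, match="constant"):
            select_fractional_polynomial(
                np.full(100, 40.0), np.r_[np.ones(50), np.zeros(50)]
            )

    def test_log_transform_and_repeated_power_design(self):
        x = np.array([10.0, 20.0, 40.0])
        cols, names = fp_design(x, (0.0,))
        assert np.allclose(cols[:, 0], np.log(x / 10.0))
        cols, names = fp_design(x, (2.0, 2.0))
        xs = x / 10.0
        assert np.allclose(cols[:, 1], xs**2 * np.log(xs))


class TestOverlap:
    def _fit(self, p, e):
        return PSFit(coefficients=pd.Series(dtype=float), propensity=p,
                     exposure=np.asarray(e))

    def test_identical_distributions_fully_overlap(self):
        p = np.tile(np.linspace(0.05, 0.6, 50), 2)
        e = np.r_[np.ones(50), np.zeros(50)].astype(int)
        rep = check_overlap(self._fit(p, e))
        assert rep.frac_exposed_outside == 0
        assert rep.frac_unexposed_outside == 0
        assert rep.adequate

    def test_separated_groups_flagged(self):
        p = np.r_[np.full(30, 0.95), np.full(30, 0.05)]
        e = np.r_[np.ones(30), np.zeros(30)].astype(int)
        rep = check_overlap(self._fit(p, e))
        assert not rep.adequate
        assert rep.frac_exposed_outside == 1.0

    def test_bin_counts_match_brute_force(self, default_cohort):
        cohort, truth, _ = default_cohort
        e = cohort.df.exposure.to_numpy()
        rep = check_overlap(self._fit(truth.true_propensity, e), bins=20)
        # independent recount by explicit interval membership
        p = truth.true_propensity
        for g, counts in ((1, rep.counts_exposed), (0, rep.counts_unexposed)):
            sub = p[e == g]
            for k in range(20):
                lo, hi = rep.bin_edges[k], rep.bin_edges[k + 1]
                manual = np.sum((sub >= lo) & (sub < hi)) if k < 19 else np.sum(
                    (sub >= lo) & (sub <= hi)
                )
                assert counts[k] == manual
        assert rep.counts_exposed.sum() == (e == 1).sum()

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            check_overlap(self._fit(np.array([0.2, 0.4]), np.array([1, 0])), bins=1)


class TestCollinearity:
    def test_duplicate_column_has_unit_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        from pslca.cohort import DesignMatrix

        dm = DesignMatrix(columns=["a", "b"], matrix=np.column_stack([x, x]),
                          references={})
        max_r, _, flag = check_collinearity(dm)
        assert max_r == pytest.approx(1.0)
        assert flag

    def test_matrix_matches_pairwise_pearson(self, default_cohort):
        from scipy import stats

        cohort, _, _ = default_cohort
        dm = encode_design(cohort, list(cohort.schema.required_columns())[2:])
        max_r, r, _ = check_collinearity(dm)
        for i in range(dm.n_columns):
            for j in range(i + 1, dm.n_columns):
                manual = stats.pearsonr(dm.matrix[:, i], dm.matrix[:, j])[0]
                assert r.iloc[i, j] == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_column_rejected(self):
        from pslca.cohort import DesignMatrix

        dm = DesignMatrix(
            columns=["a", "b"],
            matrix=np.column_stack([np.ones(50), np.arange(50.0)]),
            references={},
        )
        with pytest.raises(EstimationError, match="zero-variance"):
            check_collinearity(dm)


class TestIPTW:
    def test_weight_formulas_exact(self):
        fit = PSFit(
            coefficients=pd.Series(dtype=float),
            propensity=np.array([0.25, 0.25]),
            exposure=np.array([1, 0]),
        )
        w = compute_iptw(fit).weights
        assert w[0] == pytest.approx(4.0)
        assert w[1] == pytest.approx(4.0 / 3.0)

    @given(st.lists(st.tuples(st.floats(0.01, 0.99), st.integers(0, 1)),
                    min_size=1, max_size=50))
    def test_weights_never_below_one(self, rows):
        p = np.array([r[0] for r in rows])
        e = np.array([r[1] for r in rows])
        fit = PSFit(coefficients=pd.Series(dtype=float), propensity=p, exposure=e)
        assert (compute_iptw(fit).weights >= 1.0).all()

    def test_horvitz_thompson_group_totals(self):
        """Under the true PS, weights in each exposure group sum to ≈ n."""
        spec = sim.tlgs_like(n=50_000, seed=21)
        cohort, truth = sim.simulate_cohort(spec)
        e = cohort.df.exposure.to_numpy()
        fit = PSFit(coefficients=pd.Series(dtype=float),
                    propensity=truth.true_propensity, exposure=e)
        w = compute_iptw(fit).weights
        n = len(e)
        assert abs(w[e == 1].sum() - n) / n < 0.05
        assert abs(w[e == 0].sum() - n) / n < 0.05

    def test_degenerate_propensity_rejected(self):
        fit = PSFit(coefficients=pd.Series(dtype=float),
                    propensity=np.array([0.0, 0.5]), exposure=np.array([1, 0]))
        with pytest.raises(ValueError):
            compute_iptw(fit)


def test_pseudo_population_balances_model_covariates():
    """IPTW from the estimated PS removes the confounders' association with
    exposure: weighted standardized differences of the exposure-model
    covariates fall below 0.1 on average across replicates."""
    vals = []
    for seed in range(3):
        spec = sim.tlgs_like(n=5000, seed=seed, confounded=True)
        cohort, _ = sim.simulate_cohort(spec)
        fit = fit_ps(cohort, covariates=["gender", "age", "physical_activity"])
        w = compute_iptw(fit).weights
        e = cohort.df.exposure.to_numpy()
        d = [
            std_diff_binary(cohort.df.gender, e, weights=w),
            std_diff_continuous(cohort.df.age, e, weights=w),
            std_diff_binary(cohort.df.physical_activity, e, weights=w),
        ]
        vals.append(max(d))
    assert np.mean(vals) < 0.1
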