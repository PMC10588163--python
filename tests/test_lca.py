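"""Weighted latent-class EM: closed forms, invariants, oracle, selection."""

import itertools

import numpy as np
import pytest

from pslca import simulate as sim
from pslca.cohort import ITEM_COLUMNS
from pslca.errors import EstimationError
from pslca.lca import (
    RHO_EPS,
    _collapse,
    _posterior,
    assign_modal,
    fit_indices,
    fit_lca,
    label_classes,
    risk_label,
    sweep_classes,
)

from conftest import align_to_truth


def _weighted_ll(items, w, gamma, rho):
    pat, pw, _ = _collapse(items.astype(float), w)
    _, lse = _posterior(pat, np.asarray(gamma), np.asarray(rho))
    return float(pw @ lse)


class TestSingleClass:
    def test_rho_is_weighted_item_mean_and_ll_closed_form(self):
        rng = np.random.default_rng(0)
        items = rng.integers(0, 2, size=(300, 5))
        w = rng.uniform(0.5, 3.0, 300)
        m = fit_lca(items, weights=w, n_classes=1)
        expected_rho = (w @ items) / w.sum()
        assert np.allclose(m.gamma, [1.0])
        assert np.allclose(m.rho[0], expected_rho, atol=1e-10)
        # independent-Bernoulli closed-form log-likelihood
        ll = np.sum(
            w[:, None]
            * (items * np.log(expected_rho) + (1 - items) * np.log1p(-expected_rho))
        )
        assert m.log_likelihood == pytest.approx(ll, rel=1e-10)

    def test_all_posteriors_one(self):
        items = np.random.default_rng(1).integers(0, 2, (40, 5))
        m = fit_lca(items, n_classes=1)
        a = assign_modal(m, items)
        assert np.allclose(a.posterior, 1.0)


def test_two_pure_patterns_separate_exactly():
    items = np.r_[np.zeros((60, 5)), np.ones((40, 5))].astype(int)
    m = fit_lca(items, n_classes=2, seed=0)
    assert np.allclose(sorted(m.gamma), [0.4, 0.6], atol=1e-6)
    lo = m.rho[np.argmax(m.gamma)]  # the 60% all-zero class
    hi = m.rho[np.argmin(m.gamma)]
    assert np.allclose(lo, RHO_EPS, atol=1e-9)
    assert np.allclose(hi, 1 - RHO_EPS, atol=1e-9)


class TestFitIndices:
    def test_formula_identities_exact(self):
        for ll, p, n in [(-500.0, 17, 4857), (-65.95, 5, 1016), (-3.2, 11, 200)]:
            ix = fit_indices(ll, p, n)
            assert ix["CAIC"] - ix["BIC"] == pytest.approx(p, abs=1e-9)
            assert ix["AIC"] - ix["ABIC"] == pytest.approx(
                p * (2 - np.log((n + 2) / 24)), abs=1e-9
            )

    def test_zero_parameters_collapse_to_minus_two_ll(self):
        ix = fit_indices(-10.0, 0, 100)
        assert all(v == pytest.approx(20.0) for v in ix.values())


class TestRiskLabels:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((0.30, 0.19, 0.49, 0.06, 0.57), "low"),
            ((0.2, 0.2, 0.2, 0.2, 0.2), "no_mets"),
            ((0.78, 0.54, 0.99, 0.42, 0.69), "high"),
            ((0.6, 0.9, 0.1, 0.1, 0.1), "moderate"),
            ((0.5, 0.5, 0.5, 0.5, 0.5), "no_mets"),  # strictly greater than 0.5
        ],
    )
    def test_component_count_rule(self, row, expected):
        assert risk_label(np.array(row)) == expected

    def test_label_classes_vectorizes(self):
        rho = np.array([[0.1] * 5, [0.9] * 5])
        assert label_classes(rho) == ["no_mets", "high"]


class TestEMProperties:
    def test_weight_scaling_leaves_parameters_invariant(self):
        rng = np.random.default_rng(2)
        items = rng.integers(0, 2, (400, 5))
        w = rng.uniform(0.5, 4.0, 400)
        m1 = fit_lca(items, weights=w, n_classes=2, seed=3)
        m2 = fit_lca(items, weights=7.0 * w, n_classes=2, seed=3)
        assert np.allclose(m1.gamma, m2.gamma, atol=1e-6)
        assert np.allclose(m1.rho, m2.rho, atol=1e-5)
        assert m2.log_likelihood == pytest.approx(7 * m1.log_likelihood, rel=1e-8)
        assert m1.indices["BIC"] != pytest.approx(m2.indices["BIC"])

    def test_class_permutation_leaves_likelihood_unchanged(self, default_cohort):
        cohort, _, _ = default_cohort
        items = cohort.df[list(ITEM_COLUMNS)].to_numpy()[:800]
        m = fit_lca(items, n_classes=3, seed=1, n_starts=5)
        base = _weighted_ll(items, np.ones(len(items)), m.gamma, m.rho)
        for perm in itertools.permutations(range(3)):
            ll = _weighted_ll(
                items, np.ones(len(items)), m.gamma[list(perm)], m.rho[list(perm)]
            )
            assert ll == pytest.approx(base, rel=1e-12)

    def test_em_likelihood_dominates_coarse_grid_oracle(self):
        """On a tiny 2-class, 2-item instance the converged EM likelihood is
        at least that of every point on a coarse (γ, ρ) grid."""
        items = np.array(
            [[0, 0], [0, 0], [0, 1], [1, 1], [1, 1], [1, 0], [0, 0], [1, 1]]
        )
        m = fit_lca(items, n_classes=2, seed=0, n_starts=10)
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        best_grid = -np.inf
        w = np.ones(len(items))
        for g in grid:
            for rho_flat in itertools.product(grid, repeat=4):
                rho = np.array(rho_flat).reshape(2, 2)
                best_grid = max(
                    best_grid, _weighted_ll(items, w, np.array([g, 1 - g]), rho)
                )
        assert m.log_likelihood >= best_grid - 1e-9

    def test_determinism_across_runs(self):
        rng = np.random.default_rng(4)
        items = rng.integers(0, 2, (300, 5))
        m1 = fit_lca(items, n_classes=3, seed=11)
        m2 = fit_lca(items, n_classes=3, seed=11)
        assert np.array_equal(m1.gamma, m2.gamma)
        assert np.array_equal(m1.rho, m2.rho)

    def test_non_binary_items_rejected(self):
        with pytest.raises(EstimationError):
            fit_lca(np.array([[0, 2], [1, 0]]), n_classes=1)


class TestModalAssignment:
    def test_pure_pattern_assigned_with_high_posterior(self):
        items = np.r_[np.zeros((50, 5)), np.ones((50, 5))].astype(int)
        m = fit_lca(items, n_classes=2, seed=0)
        a = assign_modal(m, np.array([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]]))
        assert a.posterior.max(axis=1).min() > 0.99
        assert a.modal[0] != a.modal[1]
        # Bayes-rule hand recomputation for the all-ones pattern
        f = m.gamma * np.prod(
            m.rho ** np.ones(5) * (1 - m.rho) ** np.zeros(5), axis=1
        )
        assert a.posterior[0] == pytest.approx(f / f.sum(), rel=1e-9)

    def test_posterior_rows_sum_to_one(self, default_cohort):
        cohort, _, _ = default_cohort
        items = cohort.df[list(ITEM_COLUMNS)].to_numpy()
        m = fit_lca(items, n_classes=3, seed=1, n_starts=5)
        a = assign_modal(m, items)
        assert np.abs(a.posterior.sum(axis=1) - 1).max() < 1e-12


class TestSelection:
    def test_parameter_recovery_default_scenario(self, default_cohort):
        cohort, truth, spec = default_cohort
        items = cohort.df[list(ITEM_COLUMNS)].to_numpy()
        m = fit_lca(items, n_classes=3, seed=1)
        gamma_true = np.bincount(truth.true_class - 1, minlength=3) / len(cohort)
        rho_err, gamma_err = align_to_truth(m, gamma_true, spec.rho_true)
        assert rho_err < 0.1
        assert gamma_err < 0.05

    def test_independent_items_prefer_one_class(self):
        rng = np.random.default_rng(7)
        items = rng.binomial(1, [0.2, 0.4, 0.5, 0.3, 0.6], size=(2000, 5))
        table, best, _ = sweep_classes(items, max_classes=3, seed=1, n_starts=8)
        assert best == 1

    def test_index_identity_rows(self, default_cohort):
        cohort, _, _ = default_cohort
        items = cohort.df[list(ITEM_COLUMNS)].to_numpy()[:1000]
        table, best, info = sweep_classes(items, max_classes=3, seed=1, n_starts=5)
        assert np.allclose(
            table["CAIC"] - table["BIC"], table["n_parameters"], atol=1e-9
        )
        assert set(info["agreement"]) == {"CAIC", "ABIC", "AIC"}
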