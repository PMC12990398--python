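"""Trajectory model: censored density, EM fitting, criteria, selection."""

import math

import numpy as np
import pytest
from scipy import integrate

from ppdnet import gbtm
from ppdnet.datasets import (IsingParameterSpec, SyntheticCohortConfig,
                             TrajectoryGroupSpec, default_two_group_config,
                             generate_cohort)
from ppdnet.gbtm import (FitCriteria, GbtmSpec, assign_groups,
                         censored_normal_logpdf, criteria, diagnostics,
                         fit_gbtm, posterior_matrix, select_model,
                         wald_prune_orders)


# ---------------------------------------------------------------------------
# censored-normal density

def test_logpdf_at_lower_bound_is_log_half_for_centered_normal():
    assert censored_normal_logpdf(0.0, 0.0, 1.0, (0, 21)) == pytest.approx(
        math.log(0.5), abs=1e-12)


def test_logpdf_interior_matches_the_standard_normal_mode():
    val = censored_normal_logpdf(0.0, 0.0, 1.0, (-1e6, 1e6))
    assert val == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)


@pytest.mark.parametrize("mu,sigma", [(1.0, 2.0), (-0.5, 0.8), (20.0, 3.0)])
def test_censored_density_integrates_to_one(mu, sigma):
    lo, hi = 0.0, 21.0
    interior, _ = integrate.quad(
        lambda y: math.exp(censored_normal_logpdf(y, mu, sigma, (lo, hi))),
        lo + 1e-9, hi - 1e-9, limit=200)
    mass_lo = math.exp(censored_normal_logpdf(lo, mu, sigma, (lo, hi)))
    mass_hi = math.exp(censored_normal_logpdf(hi, mu, sigma, (lo, hi)))
    assert interior + mass_lo + mass_hi == pytest.approx(1.0, abs=1e-6)


def test_logpdf_domain_errors():
    with pytest.raises(ValueError, match="sigma"):
        censored_normal_logpdf(1.0, 0.0, 0.0, (0, 21))
    with pytest.raises(ValueError, match="bounds"):
        censored_normal_logpdf(-1.0, 0.0, 1.0, (0, 21))


# ---------------------------------------------------------------------------
# fitting

def _flat_cohort(n, mean, sd, seed, waves=4):
    p = 10
    spec = IsingParameterSpec(np.zeros(p), np.zeros((p, p)))
    cfg = SyntheticCohortConfig(
        n_subjects=n,
        groups=[TrajectoryGroupSpec("only", 1.0, (mean,), sd)],
        symptom_specs=[spec], standard_design=False, seed=seed,
        score_bounds=(-1e6, 1e6))
    return generate_cohort(cfg)


def test_single_group_constant_model_reduces_to_normal_mle():
    data = _flat_cohort(100, 8.0, 2.0, seed=0)
    fit = fit_gbtm(data, GbtmSpec((0,)), bounds=(-1e6, 1e6), n_starts=2)
    y = data.trajectory_table.score.to_numpy()
    assert fit.coefficients[0][0] == pytest.approx(y.mean(), abs=1e-6)
    assert fit.sigma[0] == pytest.approx(y.std(), rel=1e-4)  # ML, ddof=0


def test_two_group_linear_recovery(matched_cohort):
    fit = fit_gbtm(matched_cohort, GbtmSpec((1, 1)), n_starts=4, seed=0)
    # canonical order: higher baseline mean first = increasingly poor
    assert fit.pi[0] == pytest.approx(0.414, abs=0.05)
    truth = np.array([[6.5, 1.0], [3.5, 0.5]])
    est = np.vstack(fit.coefficients)
    assert np.sqrt(np.mean((est - truth) ** 2)) < 0.3


def test_loglik_invariant_to_subject_order(matched_cohort):
    fit = fit_gbtm(matched_cohort, GbtmSpec((1, 1)), n_starts=2, seed=0)
    rng = np.random.default_rng(0)
    shuffled = matched_cohort
    perm = rng.permutation(len(shuffled.item_table))
    import dataclasses
    data2 = dataclasses.replace(
        shuffled,
        item_table=shuffled.item_table.iloc[perm].reset_index(drop=True))
    fit2 = fit_gbtm(data2, GbtmSpec((1, 1)), n_starts=2, seed=0)
    assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)


def test_em_loglik_trace_is_monotone(matched_cohort):
    fit = fit_gbtm(matched_cohort, GbtmSpec((2, 1)), n_starts=2, seed=0,
                   strict=False)
    diffs = np.diff(fit.loglik_trace)
    assert (diffs > -1e-8).all()


# ---------------------------------------------------------------------------
# posteriors, assignment, criteria, diagnostics

def test_posterior_rows_sum_to_one_and_separate_groups(matched_cohort):
    fit = fit_gbtm(matched_cohort, GbtmSpec((1, 1)), n_starts=2, seed=0)
    post = posterior_matrix(fit, matched_cohort)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
    assert post.max(axis=1).mean() > 0.9


def test_identical_components_give_uniform_posteriors(matched_cohort):
    fit = fit_gbtm(matched_cohort, GbtmSpec((1, 1)), n_starts=2, seed=0)
    clone = fit
    clone.coefficients[1] = clone.coefficients[0].copy()
    clone.membership_logits = np.zeros(1)
    post = posterior_matrix(clone, matched_cohort)
    assert np.allclose(post, 0.5, atol=1e-12)


def test_assignment_uses_max_probability_with_low_index_ties():
    post = np.array([[0.96, 0.04], [0.5, 0.5], [0.2, 0.8]])
    assert assign_groups(post).tolist() == [0, 0, 1]


def test_criteria_reproduce_the_published_selected_model_row():
    # LL and k as printed for the selected two-group linear model
    crit = FitCriteria.from_loglik(-3574.73, 6, 372, 1488)
    assert crit.aic == pytest.approx(-3580.73, abs=0.005)
    assert crit.bic_subjects == pytest.approx(-3592.49, abs=0.005)
    assert crit.bic_observations == pytest.approx(-3596.65, abs=0.005)


def test_criteria_identities_hold_exactly_on_a_fit(matched_cohort):
    fit = fit_gbtm(matched_cohort, GbtmSpec((1, 1)), n_starts=2, seed=0)
    post = posterior_matrix(fit, matched_cohort)
    crit = criteria(fit, post)
    assert crit.aic - crit.loglik == -fit.n_params
    assert crit.bic_subjects - crit.loglik == pytest.approx(
        -0.5 * fit.n_params * math.log(fit.n_subjects), abs=1e-12)
    assert crit.bic_observations - crit.loglik == pytest.approx(
        -0.5 * fit.n_params * math.log(fit.n_observations), abs=1e-12)


def test_entropy_extremes(matched_cohort):
    fit = fit_gbtm(matched_cohort, GbtmSpec((1, 1)), n_starts=2, seed=0)
    n = fit.n_subjects
    crisp = np.zeros((n, 2))
    crisp[:, 0] = 1.0
    fit_for = lambda post: criteria(fit, post).entropy
    assert fit_for(crisp) == pytest.approx(1.0)
    assert fit_for(np.full((n, 2), 0.5)) == pytest.approx(0.0)


def test_entropy_absent_for_single_group():
    data = _flat_cohort(60, 8.0, 2.0, seed=0)
    fit = fit_gbtm(data, GbtmSpec((0,)), bounds=(-1e6, 1e6), n_starts=2)
    crit = criteria(fit, posterior_matrix(fit, data))
    assert crit.entropy is None
    assert "single group" in crit.entropy_reason


def test_occ_closed_forms():
    # AvePP 0.9 against chance 0.5 -> odds ratio 9; AvePP = pi -> 1
    fit = gbtm.GbtmFit(
        spec=GbtmSpec((0, 0)), coefficients=[np.array([8.0]),
                                             np.array([4.0])],
        sigma=np.array([1.0]), membership_logits=np.array([0.0]),
        loglik=-1.0, n_subjects=4, n_observations=4, converged=True,
        n_starts=1, bounds=(0, 21), waves_seen=np.array([0.0]))
    post = np.array([[0.9, 0.1], [0.9, 0.1], [0.5, 0.5], [0.5, 0.5]])
    labels = np.array([0, 0, 1, 1])
    table = diagnostics(fit, post, labels).table
    assert table.occ[0] == pytest.approx(9.0)
    assert table.occ[1] == pytest.approx(1.0)
    assert np.allclose(table.abs_ep_minus_p, 0.0, atol=1e-12)


def test_occ_infinite_when_classification_is_certain():
    fit = gbtm.GbtmFit(
        spec=GbtmSpec((0, 0)), coefficients=[np.array([8.0]),
                                             np.array([4.0])],
        sigma=np.array([1.0]), membership_logits=np.array([0.0]),
        loglik=-1.0, n_subjects=2, n_observations=2, converged=True,
        n_starts=1, bounds=(0, 21), waves_seen=np.array([0.0]))
    post = np.array([[1.0, 0.0], [0.0, 1.0]])
    table = diagnostics(fit, post, np.array([0, 1])).table
    assert np.isinf(table.occ[0])


# ---------------------------------------------------------------------------
# order pruning and model selection

def _two_group_cohort(slopes, n, seed, sd=1.5):
    groups = [TrajectoryGroupSpec("a", 0.5, (7.0, slopes[0]), sd),
              TrajectoryGroupSpec("b", 0.5, (3.0, slopes[1]), sd)]
    base = default_two_group_config()
    cfg = SyntheticCohortConfig(n_subjects=n, groups=groups,
                                symptom_specs=base.symptom_specs, seed=seed)
    return generate_cohort(cfg)


def test_wald_pruning_removes_null_slopes_in_most_replicates():
    hits = 0
    for seed in range(5):
        data = _two_group_cohort((0.0, 0.0), n=250, seed=seed)
        orders, _fit, _log = wald_prune_orders(data, 2, start_order=1,
                                               seed=seed, n_starts=3)
        hits += orders == (0, 0)
    assert hits >= 4


def test_wald_pruning_keeps_genuinely_linear_terms():
    for seed in range(3):
        data = _two_group_cohort((1.2, 0.6), n=300, seed=seed)
        orders, _fit, _log = wald_prune_orders(data, 2, start_order=1,
                                               seed=seed, n_starts=3)
        assert orders == (1, 1)


def test_start_order_zero_returns_unchanged(matched_cohort):
    orders, _fit, _log = wald_prune_orders(matched_cohort, 2, start_order=0,
                                           seed=0, n_starts=2)
    assert orders == (0, 0)


def test_select_model_prefers_two_linear_groups(matched_cohort):
    report = select_model(matched_cohort, k_range=(2, 3), seed=0, n_starts=3)
    row = report.candidates.iloc[report.chosen_index]
    assert row.n_groups == 2
    assert row.orders == "11"
    assert any("selected K=2" in r for r in report.fired_rules)


def test_select_model_excludes_small_groups_by_rule(matched_cohort):
    report = select_model(matched_cohort, k_range=(2, 4), seed=0, n_starts=3)
    k4 = report.candidates[report.candidates.n_groups == 4]
    if float(k4.min_share.iloc[0]) < 0.05:
        assert any("min group share" in r for r in report.fired_rules)


def test_select_model_breaks_exact_ties_by_entropy(matched_cohort):
    report = select_model(matched_cohort, k_range=(2, 2), seed=0, n_starts=2)
    assert any("tie resolved by higher entropy" in r
               for r in report.fired_rules)
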