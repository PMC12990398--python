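"""Association statistics: JZS Bayes factor, odds ratios, z-test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import nct as nct_dist
from scipy.stats import t as t_dist

from ppdnet.association import (DEPRESSION_CUTOFF, SeparationError,
                                bayes_factor_ttest, bf10_from_t,
                                build_outcome_table, coef_difference_z,
                                linear_association, logistic_association)


def _bf_oracle(t, n1, n2, r=math.sqrt(2) / 2):
    """Independent route: integrate the noncentral-t likelihood against
    the Cauchy effect-size prior directly on the effect scale."""
    nu = n1 + n2 - 2
    ne = n1 * n2 / (n1 + n2)
    s = math.sqrt(ne)

    def integrand(d):
        lik = nct_dist.pdf(t, nu, d * s)
        if math.isnan(lik):   # scipy underflow in the far tail
            lik = 0.0
        return lik * (1 / (math.pi * r)) / (1 + (d / r) ** 2)

    # the t-likelihood kills the integrand far from t/s, so a bounded
    # range loses nothing while keeping scipy's nct evaluation stable
    m1, _ = integrate.quad(integrand, -10, 10, limit=400,
                           points=[0.0, t / s])
    return m1 / t_dist.pdf(t, nu)


@pytest.mark.parametrize("t", [0.0, 0.5, 1.0, 2.0, 3.0])
@pytest.mark.parametrize("n", [20, 50, 120])
def test_bf_matches_the_effect_scale_quadrature_oracle(t, n):
    ours = bf10_from_t(t, n * n / (2 * n), 2 * n - 2)
    oracle = _bf_oracle(t, n, n)
    assert ours == pytest.approx(oracle, rel=1e-6)


def test_bf_matches_pingouin_default_bayes_factor():
    pg = pytest.importorskip("pingouin")
    got = bf10_from_t(2.5, 30 * 40 / 70, 68)
    want = float(pg.bayesfactor_ttest(2.5, 30, 40))
    assert got == pytest.approx(want, rel=1e-3)


def test_bf_is_below_one_without_an_effect():
    x = np.arange(50, dtype=float)
    assert bayes_factor_ttest(x, x.copy()) < 1.0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 1, 500)
        assert bayes_factor_ttest(a, b) < 1.0


def test_bf_monotone_in_t():
    vals = [bf10_from_t(t, 25.0, 98) for t in (0, 1, 2, 3, 4)]
    assert all(b < a for b, a in zip(vals, vals[1:]))


def test_bf_domain_errors():
    with pytest.raises(ValueError, match="pooled variance"):
        bayes_factor_ttest(np.ones(10), np.ones(10))
    with pytest.raises(ValueError, match="two observations"):
        bayes_factor_ttest(np.ones(1), np.zeros(10))


# ---------------------------------------------------------------------------
# outcome table and regressions

def _items_for_total(total):
    scores = []
    left = total
    for _ in range(10):
        take = min(3, left)
        scores.append(take)
        left -= take
    return scores


def _toy_table(n=400, or_true=1.0, seed=0, base_rate=0.25):
    rng = np.random.default_rng(seed)
    poor = rng.random(n) < 0.414
    eta = math.log(base_rate / (1 - base_rate)) + math.log(or_true) * poor
    depressed = rng.random(n) < 1 / (1 + np.exp(-eta))
    totals = np.where(depressed, 15, 8)
    items = pd.DataFrame([_items_for_total(t) for t in totals],
                         columns=[f"item{i}" for i in range(1, 11)])
    items.insert(0, "subject_id", np.arange(n))
    labels = pd.Series(np.where(poor, "poor", "good"),
                       index=pd.Index(np.arange(n), name="subject_id"))
    cov = pd.DataFrame({"subject_id": np.arange(n),
                        "age": rng.normal(30, 4, n)})
    return build_outcome_table(labels, items, cov, poor_label="poor")


def test_depression_flag_steps_exactly_at_the_cutoff():
    items = pd.DataFrame([_items_for_total(t) for t in range(31)],
                         columns=[f"item{i}" for i in range(1, 11)])
    items.insert(0, "subject_id", np.arange(31))
    labels = pd.Series(["poor"] * 31,
                       index=pd.Index(np.arange(31), name="subject_id"))
    cov = pd.DataFrame({"subject_id": np.arange(31)})
    table = build_outcome_table(labels, items, cov, poor_label="poor")
    assert (table.frame.depressed.to_numpy()
            == (np.arange(31) >= DEPRESSION_CUTOFF)).all()


def test_crude_odds_ratio_equals_the_two_by_two_closed_form():
    table = _toy_table(n=600, or_true=3.0, seed=1)
    f = table.frame
    a = ((f.poor_trajectory == 1) & (f.depressed == 1)).sum()
    b = ((f.poor_trajectory == 1) & (f.depressed == 0)).sum()
    c = ((f.poor_trajectory == 0) & (f.depressed == 1)).sum()
    d = ((f.poor_trajectory == 0) & (f.depressed == 0)).sum()
    or_, _ci, _p = logistic_association(table)
    assert or_ == pytest.approx(a * d / (b * c), abs=1e-8)


def test_odds_ratio_recovery_at_the_reported_effect_size():
    table = _toy_table(n=5000, or_true=2.75, seed=2)
    or_, ci, p = logistic_association(table)
    assert 2.4 < or_ < 3.1
    assert ci[0] < or_ < ci[1]
    assert p < 0.001


def test_null_odds_ratio_interval_covers_one():
    covered = 0
    for seed in range(40):
        table = _toy_table(n=2000, or_true=1.0, seed=100 + seed)
        _or, ci, _p = logistic_association(table)
        covered += ci[0] <= 1.0 <= ci[1]
    assert covered >= 36   # ~95% nominal coverage


def test_separation_is_reported_not_clipped():
    table = _toy_table(n=200, seed=3)
    table.frame["depressed"] = table.frame["poor_trajectory"]
    with pytest.raises(SeparationError):
        logistic_association(table)


def test_linear_coefficient_is_the_difference_of_group_means():
    table = _toy_table(n=500, or_true=2.0, seed=4)
    f = table.frame
    delta = (f.total[f.poor_trajectory == 1].mean()
             - f.total[f.poor_trajectory == 0].mean())
    b, se = linear_association(table)
    assert b == pytest.approx(delta, abs=1e-10)
    assert se > 0


def test_constant_outcome_flagged_as_zero_coefficient():
    table = _toy_table(n=100, seed=5)
    table.frame["total"] = 9.0
    assert linear_association(table) == (0.0, 0.0)


def test_rank_deficiency_names_collinear_columns():
    table = _toy_table(n=100, seed=6)
    table.frame["age_copy"] = table.frame["age"]
    with pytest.raises(ValueError, match="age"):
        linear_association(table, adjusted=True)


def test_estimates_invariant_to_row_permutation():
    table = _toy_table(n=300, or_true=2.0, seed=7)
    or1, _, _ = logistic_association(table)
    b1, se1 = linear_association(table)
    table.frame = table.frame.sample(frac=1.0, random_state=3)
    or2, _, _ = logistic_association(table)
    b2, se2 = linear_association(table)
    assert or2 == pytest.approx(or1, abs=1e-10)
    assert (b2, se2) == pytest.approx((b1, se1), abs=1e-10)


# ---------------------------------------------------------------------------
# coefficient-difference z-test

def test_z_test_reproduces_the_published_crude_comparison():
    z, p = coef_difference_z(2.99, 0.44, 2.50, 0.39)
    assert round(z, 2) == 0.83
    assert round(p, 2) == 0.40


def test_z_test_null_and_domain():
    z, p = coef_difference_z(1.5, 0.2, 1.5, 0.3)
    assert z == 0.0
    assert p == 1.0
    with pytest.raises(ValueError):
        coef_difference_z(1.0, 0.0, 1.0, 0.1)


# a small property sweep: the z-test is antisymmetric in its arguments
# and its p-value is a valid probability
try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(b1=st.floats(-50, 50), b2=st.floats(-50, 50),
           se1=st.floats(1e-3, 10), se2=st.floats(1e-3, 10))
    def test_z_test_antisymmetry_and_valid_p(b1, b2, se1, se2):
        z12, p12 = coef_difference_z(b1, se1, b2, se2)
        z21, p21 = coef_difference_z(b2, se2, b1, se1)
        assert z12 == pytest.approx(-z21, abs=1e-12)
        assert p12 == pytest.approx(p21, abs=1e-12)
        assert 0.0 <= p12 <= 1.0
except ImportError:   # hypothesis is an optional test dependency
    pass
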