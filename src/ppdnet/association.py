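"""Trajectory-depression association statistics.

Links an assigned sleep-quality trajectory to depressive symptoms:

* a Jeffreys-Zellner-Siow (default Cauchy prior) Bayes-factor t-test on
  total symptom scores between two trajectory groups;
* logistic regression of probable depression (total score >= 13) on the
  trajectory indicator, crude or adjusted for the demographic set;
* the item-7 sensitivity analysis: linear regressions of the total
  score with and without the sleep-related item, and a z-test on the
  difference of the two trajectory coefficients,
  z = (B1 - B2) / sqrt(SE1^2 + SE2^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "OutcomeTable",
    "build_outcome_table",
    "bayes_factor_ttest",
    "logistic_association",
    "linear_association",
    "coef_difference_z",
    "DEPRESSION_CUTOFF",
    "ITEM7",
]

DEPRESSION_CUTOFF = 13
ITEM7 = "item7"
_COVARIATES = ["age", "education", "employed", "urban_birthplace", "married",
               "income_high", "nulliparous", "planned_pregnancy",
               "vaginal_delivery"]


@dataclass
class OutcomeTable:
    """Per-subject outcomes and design columns for the association models."""

    frame: pd.DataFrame
    poor_label: str

    @property
    def exposure(self) -> np.ndarray:
        return self.frame["poor_trajectory"].to_numpy()


def build_outcome_table(labels: pd.Series, item_table: pd.DataFrame,
                        covariate_table: pd.DataFrame,
                        poor_label: str) -> OutcomeTable:
    """Assemble totals, the depression flag and covariate encodings.

    ``poor_label`` names the exposed trajectory; the other group is the
    reference.  Education (three levels) becomes two indicator columns;
    all other categorical covariates are already binary.
    """
    items = item_table.set_index("subject_id")
    total = items.sum(axis=1)
    total_no7 = items.drop(columns=ITEM7).sum(axis=1)
    frame = pd.DataFrame({
        "group": labels.reindex(items.index),
        "total": total,
        "total_no_item7": total_no7,
        "depressed": (total >= DEPRESSION_CUTOFF).astype(int),
    })
    frame["poor_trajectory"] = (frame.group == poor_label).astype(int)
    cov = covariate_table.set_index("subject_id").reindex(items.index)
    for name in _COVARIATES:
        if name not in cov.columns:
            continue
        if name == "education":
            frame["edu_associate"] = (cov[name] == "associate").astype(int)
            frame["edu_bachelor"] = (cov[name] == "bachelor").astype(int)
        else:
            frame[name] = pd.to_numeric(cov[name])
    return OutcomeTable(frame=frame, poor_label=poor_label)


def _covariate_columns(table: OutcomeTable) -> list[str]:
    skip = {"group", "total", "total_no_item7", "depressed",
            "poor_trajectory"}
    return [c for c in table.frame.columns if c not in skip]


# ---------------------------------------------------------------------------
# JZS Bayes factor

def bayes_factor_ttest(x, y, rscale: float = math.sqrt(2) / 2) -> float:
    """BF10 of the two-sample Jeffreys-Zellner-Siow t-test.

    The alternative places a Cauchy(0, rscale) prior on the
    standardized group difference; with the Jeffreys prior on the
    variance this reduces to a one-dimensional integral over the
    variance mixing parameter g (inverse-gamma(1/2, rscale^2/2)),
    evaluated here by adaptive quadrature on the marginal likelihood
    ratio expressed through the t statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.shape[0], y.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    nu = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / nu
    if sp2 == 0:
        raise ValueError("pooled variance is zero")
    n_eff = n1 * n2 / (n1 + n2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 / n_eff)
    return bf10_from_t(t, n_eff, nu, rscale)


def bf10_from_t(t: float, n_eff: float, nu: float,
                rscale: float = math.sqrt(2) / 2) -> float:
    """JZS BF10 from a t statistic (Rouder et al. marginal form)."""
    t2 = t * t
    r2 = rscale * rscale

    def log_m1_integrand(g):
        # t-likelihood under effect scale g times inv-gamma(1/2, r^2/2)
        c = 1.0 + n_eff * g
        log_lik = -0.5 * math.log(c) - 0.5 * (nu + 1) * math.log1p(
            t2 / (c * nu))
        log_prior = (0.5 * math.log(r2 / 2.0) - math.lgamma(0.5)
                     - 1.5 * math.log(g) - r2 / (2.0 * g))
        return log_lik + log_prior

    def integrand(u):
        # map g = u/(1-u) onto (0, 1); jacobian 1/(1-u)^2
        g = u / (1.0 - u)
        return math.exp(log_m1_integrand(g)) / (1.0 - u) ** 2

    m1, _err = integrate.quad(integrand, 0.0, 1.0, limit=200,
                              epsabs=1e-12, epsrel=1e-10)
    log_m0 = -0.5 * (nu + 1) * math.log1p(t2 / nu)
    return m1 / math.exp(log_m0)


# ---------------------------------------------------------------------------
# regression models

class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in the logistic model."""


def logistic_association(table: OutcomeTable, adjusted: bool = False):
    """Odds ratio of probable depression for the poor trajectory.

    Returns (odds ratio, (ci_low, ci_high), p) from a maximum-likelihood
    logit with a Wald interval on the log-odds scale.  Raises
    :class:`SeparationError` instead of silently reporting a diverging
    estimate.
    """
    frame = table.frame
    y = frame["depressed"].to_numpy()
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    cols = ["poor_trajectory"] + (_covariate_columns(table) if adjusted
                                  else [])
    X = sm.add_constant(frame[cols].to_numpy(dtype=float))
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise SeparationError(str(exc)) from exc
    coef = res.params[1]
    se = res.bse[1]
    if not np.isfinite(se) or abs(coef) > 15:
        raise SeparationError("diverging trajectory coefficient")
    ci = (math.exp(coef - 1.959963984540054 * se),
          math.exp(coef + 1.959963984540054 * se))
    return math.exp(coef), ci, float(res.pvalues[1])


def linear_association(table: OutcomeTable, drop_item7: bool = False,
                       adjusted: bool = False):
    """OLS coefficient (and SE) of the poor-trajectory indicator.

    The outcome is the symptom total, optionally excluding the
    sleep-related item 7.  A constant outcome returns B = 0, SE = 0.
    Rank-deficient designs raise with the offending columns named.
    """
    frame = table.frame
    y = frame["total_no_item7" if drop_item7 else "total"].to_numpy(float)
    cols = ["poor_trajectory"] + (_covariate_columns(table) if adjusted
                                  else [])
    X = sm.add_constant(frame[cols].to_numpy(dtype=float))
    if y.min() == y.max():
        return 0.0, 0.0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for i, c in enumerate(["const"] + cols):
            reduced = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns include {bad}")
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])


def coef_difference_z(b1: float, se1: float, b2: float, se2: float):
    """z-test for equality of two regression coefficients.

    z = (B1 - B2) / sqrt(SE1^2 + SE2^2), two-sided normal p.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / math.sqrt(se1 * se1 + se2 * se2)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)
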