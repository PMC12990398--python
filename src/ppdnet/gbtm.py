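"""Group-based trajectory modelling with a censored-normal outcome.

A finite mixture of polynomial mean trajectories: subject i in latent
group j has score y_it = sum_d beta_jd t^d + e_it at wave t, with
e_it ~ N(0, sigma^2) and the observed score censored to the instrument
bounds (mass accumulates at the scale floor and ceiling).  Within-group
random variation in the growth parameters is fixed at zero, so groups
capture all heterogeneity.  Subjects contribute the likelihood of their
observed waves only (full-information maximum likelihood), so partially
missing follow-up requires no listwise deletion.

Fitting is EM with a quasi-Newton M-step; model choice follows the
conventional workflow: information criteria reported on the
log-likelihood scale (higher, i.e. closer to zero, is better), entropy,
a minimum group share, and the classification adequacy diagnostics
AvePP, OCC and |EP - P|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp
from scipy.stats import norm

_LOG_SQRT_2PI = 0.9189385332046727


def _norm_logpdf(z):
    return -0.5 * z * z - _LOG_SQRT_2PI

__all__ = [
    "GbtmSpec",
    "GbtmFit",
    "FitCriteria",
    "GroupDiagnostics",
    "ModelSelectionReport",
    "FitError",
    "censored_normal_logpdf",
    "fit_gbtm",
    "posterior_matrix",
    "assign_groups",
    "criteria",
    "diagnostics",
    "wald_prune_orders",
    "select_model",
]


class FitError(RuntimeError):
    """Raised when no start converges; carries the best incumbent fit."""

    def __init__(self, message: str, incumbent=None):
        super().__init__(message)
        self.incumbent = incumbent


@dataclass(frozen=True)
class GbtmSpec:
    """Candidate model: per-group polynomial orders, shared residual SD."""

    orders: tuple[int, ...]
    shared_residual_sd: bool = True

    def __post_init__(self) -> None:
        if len(self.orders) < 1:
            raise ValueError("at least one group required")
        if any(d < 0 or d > 3 for d in self.orders):
            raise ValueError("polynomial orders must be 0..3")

    @property
    def n_groups(self) -> int:
        return len(self.orders)

    def n_params(self) -> int:
        k = sum(d + 1 for d in self.orders)
        k += 1 if self.shared_residual_sd else self.n_groups
        k += self.n_groups - 1
        return k


@dataclass
class GbtmFit:
    spec: GbtmSpec
    coefficients: list[np.ndarray]
    sigma: np.ndarray                 # length 1 (shared) or K
    membership_logits: np.ndarray     # length K-1, reference group last
    loglik: float
    n_subjects: int
    n_observations: int
    converged: bool
    n_starts: int
    bounds: tuple[float, float]
    waves_seen: np.ndarray
    degenerate: bool = False
    n_iter: int = 0
    loglik_trace: np.ndarray | None = None

    @property
    def n_groups(self) -> int:
        return self.spec.n_groups

    @property
    def pi(self) -> np.ndarray:
        z = np.concatenate([self.membership_logits, [0.0]])
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()

    @property
    def n_params(self) -> int:
        return self.spec.n_params()

    def sigma_for(self, j: int) -> float:
        return float(self.sigma[0 if self.spec.shared_residual_sd else j])

    def trajectory_at(self, j: int, t: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients[j][::-1], np.asarray(t, float))


@dataclass
class FitCriteria:
    loglik: float
    aic: float
    bic_subjects: float
    bic_observations: float
    entropy: float | None
    entropy_reason: str | None = None

    @classmethod
    def from_loglik(cls, loglik: float, n_params: int, n_subjects: int,
                    n_observations: int,
                    entropy: float | None = None) -> "FitCriteria":
        """Criteria from a log-likelihood and parameter count.

        Conventions on the log-likelihood scale: AIC = LL - k and
        BIC_N = LL - (k/2) ln N, so better models are closer to zero.
        """
        return cls(
            loglik=loglik,
            aic=loglik - n_params,
            bic_subjects=loglik - 0.5 * n_params * math.log(n_subjects),
            bic_observations=loglik - 0.5 * n_params * math.log(
                n_observations),
            entropy=entropy,
        )


@dataclass
class GroupDiagnostics:
    table: pd.DataFrame   # group, pi (EP), assigned share (P), AvePP, OCC, |EP-P|

    def adequate(self, avepp_min: float = 0.7, occ_min: float = 5.0,
                 ep_p_max: float = 0.05) -> bool:
        t = self.table
        return bool((t.avepp > avepp_min).all() and (t.occ >= occ_min).all()
                    and (t.abs_ep_minus_p < ep_p_max).all())


@dataclass
class ModelSelectionReport:
    candidates: pd.DataFrame
    chosen: GbtmFit
    chosen_index: int
    fired_rules: list[str]


# ---------------------------------------------------------------------------
# censored-normal component density

def censored_normal_logpdf(y, mu, sigma, bounds):
    """Log-density of a normal censored to ``bounds``.

    Observations at the lower bound contribute log Phi((L-mu)/sigma),
    at the upper bound log(1 - Phi((U-mu)/sigma)), interior points the
    usual normal density.  ``y`` must lie within the bounds.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    lo, hi = bounds
    if np.any(y < lo) or np.any(y > hi):
        raise ValueError("observations outside the censoring bounds")
    z = (y - mu) / sigma
    out = _norm_logpdf(z) - np.log(sigma)
    out = np.where(y <= lo, log_ndtr((lo - mu) / sigma), out)
    out = np.where(y >= hi, log_ndtr(-(hi - mu) / sigma), out)
    return out


# ---------------------------------------------------------------------------
# internal data layout

class _Stacked:
    """Observation-level arrays extracted once per dataset."""

    def __init__(self, dataset, bounds):
        traj = dataset.trajectory_table
        subjects = dataset.subjects()
        index = {s: i for i, s in enumerate(subjects)}
        self.subj = traj["subject_id"].map(index).to_numpy()
        self.t = traj["wave"].to_numpy(dtype=float)
        self.y = traj["score"].to_numpy(dtype=float)
        keep = ~np.isnan(self.y)
        self.subj, self.t, self.y = (a[keep] for a in
                                     (self.subj, self.t, self.y))
        self.n_subjects = len(subjects)
        self.n_obs = self.y.shape[0]
        self.bounds = bounds
        counts = np.bincount(self.subj, minlength=self.n_subjects)
        if (counts == 0).any():
            raise ValueError("every subject needs at least one observed wave")
        self.waves = np.unique(self.t)
        lo, hi = bounds
        self.at_lo = self.y <= lo
        self.at_hi = self.y >= hi
        self._tiles: dict[int, tuple] = {}

    def designs(self, orders):
        return [np.vander(self.t, d + 1, increasing=True) for d in orders]

    def tiled(self, K):
        """Arrays repeated K times for stacked all-group evaluation."""
        if K not in self._tiles:
            self._tiles[K] = (
                np.tile(self.y, K),
                np.tile(self.at_lo, K),
                np.tile(self.at_hi, K),
                np.tile(self.subj, K) + np.repeat(
                    np.arange(K) * self.n_subjects, self.n_obs),
            )
        return self._tiles[K]


def _pack(coeffs, log_sigma):
    return np.concatenate([np.concatenate(coeffs), np.atleast_1d(log_sigma)])


def _unpack(theta, orders, shared):
    coeffs, pos = [], 0
    for d in orders:
        coeffs.append(theta[pos:pos + d + 1])
        pos += d + 1
    return coeffs, theta[pos:]


def _stacked_mu_sigma(stacked, designs, coeffs, log_sigma, shared):
    """Concatenated per-group means and the matching sigma vector."""
    K = len(coeffs)
    mu = np.concatenate([designs[j] @ coeffs[j] for j in range(K)])
    if shared:
        sigma = float(np.exp(log_sigma[0]))
    else:
        sigma = np.repeat(np.exp(log_sigma), stacked.n_obs)
    return mu, sigma


def _censored_parts(y, mu, sigma, at_lo, at_hi, lo, hi, want_grads):
    """Vectorized censored-normal log-density (and gradients) via masks."""
    z = (y - mu) / sigma
    logpdf = _norm_logpdf(z) - np.log(sigma)
    dmu = dls = None
    if want_grads:
        dmu = z / sigma
        dls = z * z - 1.0
    if at_lo.any():
        sig = sigma[at_lo] if np.ndim(sigma) else sigma
        a = (lo - mu[at_lo]) / sig
        lcdf = log_ndtr(a)
        logpdf[at_lo] = lcdf
        if want_grads:
            ratio = np.exp(_norm_logpdf(a) - lcdf)        # phi/Phi
            dmu[at_lo] = -ratio / sig
            dls[at_lo] = -a * ratio
    if at_hi.any():
        sig = sigma[at_hi] if np.ndim(sigma) else sigma
        b = (hi - mu[at_hi]) / sig
        lsf = log_ndtr(-b)
        logpdf[at_hi] = lsf
        if want_grads:
            ratio = np.exp(_norm_logpdf(b) - lsf)         # phi/(1-Phi)
            dmu[at_hi] = ratio / sig
            dls[at_hi] = b * ratio
    return logpdf, dmu, dls


def _component_loglik(stacked, designs, coeffs, log_sigma, shared):
    """n_subjects x K matrix of per-subject component log-likelihoods."""
    K = len(coeffs)
    lo, hi = stacked.bounds
    y, at_lo, at_hi, subj = stacked.tiled(K)
    mu, sigma = _stacked_mu_sigma(stacked, designs, coeffs, log_sigma, shared)
    logf, _, _ = _censored_parts(y, mu, sigma, at_lo, at_hi, lo, hi, False)
    sums = np.bincount(subj, weights=logf,
                       minlength=K * stacked.n_subjects)
    return sums.reshape(K, stacked.n_subjects).T


def _weighted_negloglik_and_grad(theta, stacked, designs, orders, shared, W):
    """M-step objective: -sum_ij w_ij log f_ij, with analytic gradient."""
    coeffs, log_sigma = _unpack(theta, orders, shared)
    K = len(orders)
    lo, hi = stacked.bounds
    n = stacked.n_obs
    y, at_lo, at_hi, _subj = stacked.tiled(K)
    mu, sigma = _stacked_mu_sigma(stacked, designs, coeffs, log_sigma, shared)
    logf, dmu, dls = _censored_parts(y, mu, sigma, at_lo, at_hi, lo, hi,
                                     True)
    w = W[stacked.subj].T.ravel()
    total = -float(w @ logf)
    grad = np.zeros_like(theta)
    wdmu = w * dmu
    pos = 0
    for j in range(K):
        d = orders[j]
        grad[pos:pos + d + 1] = -(designs[j].T @ wdmu[j * n:(j + 1) * n])
        pos += d + 1
    wdls = w * dls
    if shared:
        grad[pos] = -float(wdls.sum())
    else:
        grad[pos:] = -wdls.reshape(K, n).sum(axis=1)
    return total, grad


def _em(stacked, spec, coeffs, log_sigma, pi, max_iter, tol, m_maxiter=25):
    designs = stacked.designs(spec.orders)
    shared = spec.shared_residual_sd
    orders = spec.orders
    trace = []
    ll_prev = -np.inf
    converged = False
    theta = _pack(coeffs, log_sigma)
    for it in range(max_iter):
        L = _component_loglik(stacked, designs, *_unpack(theta, orders,
                                                         shared), shared)
        logpost = np.log(np.maximum(pi, 1e-300)) + L
        ll = float(logsumexp(logpost, axis=1).sum())
        trace.append(ll)
        W = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
        if ll - ll_prev < tol and it > 0:
            converged = ll - ll_prev > -1e-6
            break
        ll_prev = ll
        pi = W.mean(axis=0)
        res = optimize.minimize(
            _weighted_negloglik_and_grad, theta, jac=True, method="L-BFGS-B",
            args=(stacked, designs, orders, shared, W),
            options={"maxiter": m_maxiter})
        theta = res.x
    coeffs, log_sigma = _unpack(theta, orders, shared)
    return coeffs, log_sigma, pi, ll, np.asarray(trace), converged, it + 1


def _initial_partitions(stacked, K, n_starts, rng):
    """Subject partitions: quantile cuts on jittered subject means and
    random assignments, in alternation."""
    sums = np.bincount(stacked.subj, weights=stacked.y,
                       minlength=stacked.n_subjects)
    counts = np.bincount(stacked.subj, minlength=stacked.n_subjects)
    means = sums / counts
    spread = means.std() + 1e-9
    parts = []
    for s in range(n_starts):
        if s % 3 == 2:
            parts.append(rng.integers(K, size=stacked.n_subjects))
        else:
            jitter = 0.0 if s == 0 else rng.normal(0, 0.3 * spread,
                                                   size=means.shape)
            ranks = np.argsort(np.argsort(means + jitter))
            parts.append((ranks * K) // stacked.n_subjects)
    return parts


def _init_from_partition(stacked, spec, part):
    designs = stacked.designs(spec.orders)
    K = spec.n_groups
    coeffs = []
    resid_ss, resid_n = 0.0, 0
    for j in range(K):
        members = np.isin(stacked.subj, np.flatnonzero(part == j))
        D = designs[j][members] if members.any() else designs[j]
        yj = stacked.y[members] if members.any() else stacked.y
        beta, *_ = np.linalg.lstsq(D, yj, rcond=None)
        coeffs.append(beta)
        r = yj - D @ beta
        resid_ss += float(r @ r)
        resid_n += r.shape[0]
    sigma = math.sqrt(max(resid_ss / max(resid_n, 1), 1e-4))
    n_sig = 1 if spec.shared_residual_sd else K
    log_sigma = np.full(n_sig, math.log(sigma))
    pi = np.bincount(part, minlength=K).astype(float)
    pi = np.maximum(pi, 1.0)
    pi /= pi.sum()
    return coeffs, log_sigma, pi


def _canonicalize(coeffs, log_sigma, pi, spec, baseline_t):
    """Relabel groups by fitted mean at the baseline wave, descending."""
    base = np.array([np.polyval(c[::-1], baseline_t) for c in coeffs])
    order = np.argsort(-base, kind="stable")
    coeffs = [coeffs[j] for j in order]
    orders = tuple(spec.orders[j] for j in order)
    if not spec.shared_residual_sd:
        log_sigma = log_sigma[order]
    pi = pi[order]
    return coeffs, log_sigma, pi, replace(spec, orders=orders)


def fit_gbtm(dataset, spec: GbtmSpec, bounds=(0.0, 21.0), max_iter=300,
             tol=1e-8, n_starts=10, seed=0, init=None,
             strict: bool = True) -> GbtmFit:
    """Maximum-likelihood censored-normal trajectory mixture.

    Multi-start EM: quantile partitions of jittered subject means plus
    random partitions; the best final log-likelihood wins.  Groups are
    relabelled in decreasing order of fitted baseline mean so that group
    identity is stable across runs.  ``init`` (a GbtmFit) adds a warm
    start to the start list.  With ``strict`` false, a fit that hit the
    iteration cap is returned (flagged) instead of raising.
    """
    stacked = _Stacked(dataset, bounds)
    K = spec.n_groups
    if K > stacked.n_subjects:
        raise ValueError("more groups than subjects")
    rng = np.random.default_rng(seed)

    starts = []
    if init is not None and init.n_groups == K:
        starts.append((list(init.coefficients), np.log(init.sigma),
                       init.pi.copy()))
    for part in _initial_partitions(stacked, K, n_starts, rng):
        starts.append(_init_from_partition(stacked, spec, part))

    best = None
    for coeffs0, ls0, pi0 in starts:
        coeffs0 = [np.resize(np.asarray(c, float), d + 1)
                   for c, d in zip(coeffs0, spec.orders)]
        try:
            out = _em(stacked, spec, coeffs0, ls0, pi0, max_iter, tol)
        except (np.linalg.LinAlgError, FloatingPointError):
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:
        raise FitError("all EM starts failed")
    coeffs, log_sigma, pi, ll, trace, converged, n_iter = best

    baseline_t = float(stacked.waves.min())
    coeffs, log_sigma, pi, spec_c = _canonicalize(coeffs, log_sigma, pi,
                                                  spec, baseline_t)
    pi = np.maximum(pi, 1e-300)
    logits = np.log(pi[:-1]) - np.log(pi[-1])
    fit = GbtmFit(
        spec=spec_c, coefficients=[np.asarray(c) for c in coeffs],
        sigma=np.exp(log_sigma), membership_logits=logits,
        loglik=ll, n_subjects=stacked.n_subjects,
        n_observations=stacked.n_obs, converged=converged,
        n_starts=len(starts), bounds=tuple(bounds),
        waves_seen=stacked.waves, degenerate=bool((pi < 1e-6).any()),
        n_iter=n_iter, loglik_trace=trace)
    if not converged and strict:
        raise FitError("EM did not converge on any start", incumbent=fit)
    return fit


def posterior_matrix(fit: GbtmFit, dataset) -> np.ndarray:
    """Posterior membership probabilities, rows summing to one."""
    stacked = _Stacked(dataset, fit.bounds)
    designs = stacked.designs(fit.spec.orders)
    L = _component_loglik(stacked, designs, fit.coefficients,
                          np.log(fit.sigma), fit.spec.shared_residual_sd)
    logpost = np.log(fit.pi) + L
    return np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))


def assign_groups(post: np.ndarray) -> np.ndarray:
    """Maximum-probability rule; ties resolve to the lowest group index."""
    return np.argmax(post, axis=1)


def criteria(fit: GbtmFit, post: np.ndarray | None = None) -> FitCriteria:
    """Information criteria and, for K >= 2, the normalized entropy."""
    entropy = None
    reason = None
    K = fit.n_groups
    if K < 2:
        reason = "entropy undefined for a single group"
    elif post is None:
        reason = "posterior matrix not supplied"
    else:
        p = np.clip(post, 1e-300, 1.0)
        ent = float(-(p * np.log(p)).sum())
        entropy = 1.0 - ent / (fit.n_subjects * math.log(K))
    crit = FitCriteria.from_loglik(fit.loglik, fit.n_params,
                                   fit.n_subjects, fit.n_observations,
                                   entropy)
    crit.entropy_reason = reason
    return crit


def diagnostics(fit: GbtmFit, post: np.ndarray,
                labels: np.ndarray) -> GroupDiagnostics:
    """Classification adequacy: AvePP, OCC and |EP - P| per group.

    OCC compares the assignment odds implied by AvePP with the chance
    odds implied by the estimated group probability, using unrounded
    values throughout.  A group with AvePP exactly 1 gets infinite OCC.
    """
    K = fit.n_groups
    pi = fit.pi
    rows = []
    for j in range(K):
        members = labels == j
        if not members.any():
            raise ValueError(f"group {j} has no assigned members")
        avepp = float(post[members, j].mean())
        share = float(members.mean())
        if avepp >= 1.0:
            occ = math.inf
        else:
            occ = (avepp / (1 - avepp)) / (pi[j] / (1 - pi[j]))
        rows.append((j, pi[j], share, avepp, occ, abs(pi[j] - share)))
    return GroupDiagnostics(pd.DataFrame(
        rows, columns=["group", "ep", "p", "avepp", "occ",
                       "abs_ep_minus_p"]))


# ---------------------------------------------------------------------------
# inference on trajectory terms

def _full_score(fit: GbtmFit, stacked) -> np.ndarray:
    """Analytic score of the mixture log-likelihood at the fit's params.

    Parameter order: group coefficients, log sigma(s), membership
    logits (reference group last).
    """
    designs = stacked.designs(fit.spec.orders)
    shared = fit.spec.shared_residual_sd
    L = _component_loglik(stacked, designs, fit.coefficients,
                          np.log(fit.sigma), shared)
    logpost = np.log(fit.pi) + L
    W = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
    neg, grad = _weighted_negloglik_and_grad(
        _pack(fit.coefficients, np.log(fit.sigma)), stacked, designs,
        fit.spec.orders, shared, W)
    score = -grad
    logit_score = (W - fit.pi).sum(axis=0)[:-1]
    return np.concatenate([score, logit_score])


def _observed_information(fit: GbtmFit, stacked, step=1e-5):
    """Observed information by central differences of the analytic score."""
    theta0 = np.concatenate([_pack(fit.coefficients, np.log(fit.sigma)),
                             fit.membership_logits])
    dim = theta0.shape[0]
    n_sig = 1 if fit.spec.shared_residual_sd else fit.n_groups
    n_coef = sum(d + 1 for d in fit.spec.orders)

    def score_at(theta):
        coeffs, log_sigma = _unpack(theta[:n_coef + n_sig], fit.spec.orders,
                                    fit.spec.shared_residual_sd)
        logits = theta[n_coef + n_sig:]
        z = np.concatenate([logits, [0.0]])
        z = z - z.max()
        pi = np.exp(z) / np.exp(z).sum()
        f = replace(fit, coefficients=list(coeffs),
                    sigma=np.exp(log_sigma),
                    membership_logits=np.asarray(logits))
        # pi is a property; replace logits is enough
        return _full_score(f, stacked)

    H = np.empty((dim, dim))
    for d in range(dim):
        e = np.zeros(dim)
        h = step * max(1.0, abs(theta0[d]))
        e[d] = h
        H[:, d] = (score_at(theta0 + e) - score_at(theta0 - e)) / (2 * h)
    H = 0.5 * (H + H.T)
    return -H


def wald_prune_orders(dataset, n_groups: int, start_order: int = 3,
                      alpha: float = 0.05, bounds=(0.0, 21.0),
                      n_starts: int = 6, seed: int = 0,
                      max_iter=300, tol=1e-7):
    """Backward pruning of trajectory terms by Wald tests.

    Starting from ``start_order`` in every group, repeatedly tests each
    group's highest-order coefficient (observed-information standard
    errors) and drops the least significant one while its two-sided p
    exceeds ``alpha``, refitting after each drop.  Falls back to a
    likelihood-ratio test when the information matrix is singular.
    Returns (orders, fit, log of decisions).
    """
    orders = [min(start_order, 3)] * n_groups
    log = []
    fit = fit_gbtm(dataset, GbtmSpec(tuple(orders)), bounds=bounds,
                   n_starts=n_starts, seed=seed, max_iter=max_iter, tol=tol,
                   strict=False)
    while True:
        orders = list(fit.spec.orders)
        stacked = _Stacked(dataset, bounds)
        candidates = [j for j in range(n_groups) if orders[j] > 0]
        if not candidates:
            break
        pvals = {}
        try:
            info = _observed_information(fit, stacked)
            cov = np.linalg.inv(info)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            offsets = np.cumsum([0] + [d + 1 for d in orders])
            for j in candidates:
                top = offsets[j] + orders[j]
                se = math.sqrt(cov[top, top])
                z = fit.coefficients[j][-1] / se
                pvals[j] = 2 * norm.sf(abs(z))
        except np.linalg.LinAlgError:
            log.append("information matrix singular: "
                       "likelihood-ratio fallback")
            from scipy.stats import chi2

            for j in candidates:
                reduced = list(orders)
                reduced[j] -= 1
                rfit = fit_gbtm(dataset, GbtmSpec(tuple(reduced)),
                                bounds=bounds, n_starts=n_starts, seed=seed,
                                max_iter=max_iter, tol=tol, init=fit,
                                strict=False)
                lr = 2 * (fit.loglik - rfit.loglik)
                pvals[j] = float(chi2.sf(max(lr, 0.0), 1))
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            log.append("all top-order terms significant; stop")
            break
        reduced = list(orders)
        reduced[worst] -= 1
        log.append(f"dropped order-{orders[worst]} term of group {worst} "
                   f"(p = {pvals[worst]:.3f})")
        fit = fit_gbtm(dataset, GbtmSpec(tuple(reduced)), bounds=bounds,
                       n_starts=n_starts, seed=seed, max_iter=max_iter,
                       tol=tol, init=fit, strict=False)
    return tuple(fit.spec.orders), fit, log


def _bic_prune_orders(dataset, n_groups, start_order, bounds, n_starts,
                      seed, max_iter, tol):
    """Backward pruning by subject-count BIC (higher on the LL scale wins)."""
    fit = fit_gbtm(dataset, GbtmSpec((min(start_order, 3),) * n_groups),
                   bounds=bounds, n_starts=n_starts, seed=seed,
                   max_iter=max_iter, tol=tol, strict=False)
    log = []
    improved = True
    while improved:
        improved = False
        orders = list(fit.spec.orders)
        bic = criteria(fit).bic_subjects
        for j in range(n_groups):
            if orders[j] == 0:
                continue
            reduced = list(orders)
            reduced[j] -= 1
            rfit = fit_gbtm(dataset, GbtmSpec(tuple(reduced)), bounds=bounds,
                            n_starts=1, seed=seed,
                            max_iter=max_iter, tol=tol, init=fit,
                            strict=False)
            rbic = criteria(rfit).bic_subjects
            if rbic >= bic:
                log.append(f"dropped order-{orders[j]} term of group {j} "
                           f"(BIC {bic:.2f} -> {rbic:.2f})")
                fit, bic, orders = rfit, rbic, reduced
                improved = True
    return tuple(fit.spec.orders), fit, log


def select_model(dataset, k_range=(2, 3, 4), start_order: int = 3,
                 order_selection: str = "bic", min_share: float = 0.05,
                 bounds=(0.0, 21.0), n_starts: int = 6, seed: int = 0,
                 max_iter=120, tol=1e-6) -> ModelSelectionReport:
    """Fit candidates over ``k_range``, prune orders, apply selection rules.

    Candidates violating the minimum group share are excluded; survivors
    are ranked by subject-count BIC on the log-likelihood scale (higher,
    i.e. closest to zero, wins); near-ties (within 1e-6) go to the higher
    entropy.  If every candidate violates the share rule the best-BIC
    candidate is returned with a warning rule fired.
    """
    prune = {"bic": _bic_prune_orders,
             "wald": lambda *a: wald_prune_orders(
                 a[0], a[1], a[2], 0.05, a[3], a[4], a[5], a[6], a[7])}
    if order_selection not in prune:
        raise ValueError("order_selection must be 'bic' or 'wald'")

    rows, fits, rules = [], [], []
    for K in k_range:
        orders, fit, _log = prune[order_selection](
            dataset, K, start_order, bounds, n_starts, seed, max_iter, tol)
        post = posterior_matrix(fit, dataset)
        labels = assign_groups(post)
        crit = criteria(fit, post)
        try:
            diag = diagnostics(fit, post, labels)
            adequate = diag.adequate()
        except ValueError:
            adequate = False
        share = float(fit.pi.min())
        rows.append({
            "n_groups": K,
            "orders": "".join(str(d) for d in orders),
            "loglik": crit.loglik, "aic": crit.aic,
            "bic_subjects": crit.bic_subjects,
            "bic_observations": crit.bic_observations,
            "entropy": crit.entropy, "min_share": share,
            "adequate": adequate,
        })
        fits.append(fit)

    table = pd.DataFrame(rows)
    eligible = table.index[table.min_share >= min_share].tolist()
    for i in table.index:
        if i not in eligible:
            rules.append(
                f"candidate K={table.n_groups[i]} excluded: min group "
                f"share {table.min_share[i]:.3f} < {min_share}")
    if not eligible:
        rules.append("no candidate satisfies the minimum group share; "
                     "returning best BIC with warning")
        eligible = table.index.tolist()

    best = max(eligible, key=lambda i: table.bic_subjects[i])
    near = [i for i in eligible
            if abs(table.bic_subjects[i] - table.bic_subjects[best]) < 1e-6]
    if len(near) > 1:
        best = max(near, key=lambda i: (table.entropy[i] or 0.0))
        rules.append("BIC tie resolved by higher entropy")
    rules.append(
        f"selected K={table.n_groups[best]} orders {table.orders[best]} "
        f"by BIC (log-likelihood scale, closest to zero)")
    return ModelSelectionReport(candidates=table, chosen=fits[best],
                                chosen_index=int(best), fired_rules=rules)
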