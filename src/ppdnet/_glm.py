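"""L1-penalized logistic regression over a regularization path.

Proximal Newton coordinate descent: each outer step builds a penalized
quadratic model from the exact gradient at the current iterate plus a
weighted Gram curvature, and solves it by cyclic coordinate descent.  The
curvature is refreshed lazily (warm starts along the descending lambda
path keep it accurate) and affects convergence speed only, never the
fixed point, which is determined by the exact gradient entering each
quadratic model.  Convergence is declared when the penalized objective
stops improving and the coefficient update is small.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["logistic_lasso_path", "lambda_path"]


@njit(cache=True, fastmath=True)
def _path_kernel(XC, y, lambdas, tol, max_outer, max_inner):
    m, n = XC.shape
    n_lam = lambdas.shape[0]
    inv_n = 1.0 / n

    ybar = np.mean(y)
    p0 = min(max(ybar, 0.5 * inv_n), 1.0 - 0.5 * inv_n)
    beta = np.zeros(m)
    b0 = np.log(p0 / (1.0 - p0))

    coefs = np.zeros((n_lam, m))
    intercepts = np.zeros(n_lam)
    logliks = np.zeros(n_lam)

    eta = np.zeros(n)                 # XC.T @ beta, maintained incrementally
    resid = np.empty(n)
    wvec = np.empty(n)
    grad = np.empty(m)
    Xw = np.empty((m, m))             # weighted Gram (curvature model)
    swx = np.empty(m)
    sw = 0.25
    have_gram = False
    db = np.empty(m)
    moved = 1.0

    for li in range(n_lam):
        lam = lambdas[li]
        obj_prev = 1e300
        ll = 0.0
        for outer in range(max_outer):
            g0 = 0.0
            ll = 0.0
            refresh = (not have_gram) or (outer == 0 and li % 3 == 0) \
                or outer == 2 or outer == 5 or outer >= 8
            if refresh:
                sw = 0.0
            for i in range(n):
                e = eta[i] + b0
                p = 1.0 / (1.0 + np.exp(-e))
                if e > 0.0:
                    ll += y[i] * e - e - np.log1p(np.exp(-e))
                else:
                    ll += y[i] * e - np.log1p(np.exp(e))
                r = p - y[i]
                resid[i] = r
                g0 += r
                if refresh:
                    pw = p * (1.0 - p)
                    if pw < 1e-6:
                        pw = 1e-6
                    wvec[i] = pw
                    sw += pw
            g0 *= inv_n
            l1 = 0.0
            for j in range(m):
                l1 += np.abs(beta[j])
            obj = -ll * inv_n + lam * l1
            if outer > 0 and obj_prev - obj < tol and moved < 3e2 * tol:
                break
            obj_prev = obj
            for j in range(m):
                s = 0.0
                for i in range(n):
                    s += XC[j, i] * resid[i]
                grad[j] = s * inv_n
            if refresh:
                sw *= inv_n
                for j in range(m):
                    s = 0.0
                    for i in range(n):
                        s += wvec[i] * XC[j, i]
                    swx[j] = s * inv_n
                    for k in range(j, m):
                        s2 = 0.0
                        for i in range(n):
                            s2 += wvec[i] * XC[j, i] * XC[k, i]
                        Xw[j, k] = s2 * inv_n
                        Xw[k, j] = s2 * inv_n
                have_gram = True

            # coordinate descent on the quadratic model
            for j in range(m):
                db[j] = 0.0
            db0 = 0.0
            itol = 0.02 * moved
            if itol < 0.01 * tol:
                itol = 0.01 * tol
            for _inner in range(max_inner):
                delta = 0.0
                gd = g0 + sw * db0
                for j in range(m):
                    gd += swx[j] * db[j]
                step = -gd / sw
                db0 += step
                if np.abs(step) > delta:
                    delta = np.abs(step)
                for j in range(m):
                    h = Xw[j, j]
                    if h <= 1e-12:
                        continue
                    gd = grad[j] + swx[j] * db0
                    for k in range(m):
                        gd += Xw[j, k] * db[k]
                    uj = beta[j] + db[j] - gd / h
                    th = lam / h
                    if uj > th:
                        new = uj - th
                    elif uj < -th:
                        new = uj + th
                    else:
                        new = 0.0
                    step = new - (beta[j] + db[j])
                    if np.abs(step) > delta:
                        delta = np.abs(step)
                    db[j] += step
                if delta < itol:
                    break
            moved = np.abs(db0)
            b0 += db0
            for j in range(m):
                if np.abs(db[j]) > moved:
                    moved = np.abs(db[j])
                beta[j] += db[j]
                if db[j] != 0.0:
                    d = db[j]
                    for i in range(n):
                        eta[i] += XC[j, i] * d

        intercepts[li] = b0
        logliks[li] = ll
        for j in range(m):
            coefs[li, j] = beta[j]
    return intercepts, coefs, logliks


def lambda_path(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                min_ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced path from the maximum absolute score covariance."""
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    # small headroom so the first path point is exactly the empty model
    lam_max *= 1.0 + 1e-6
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def logistic_lasso_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                        tol: float = 1e-7, max_outer: int = 200,
                        max_inner: int = 500):
    """Fit the whole path; returns (intercepts, coefficients, log-likelihoods).

    ``coefficients`` has shape (len(lambdas), X.shape[1]); entries are exact
    zeros when a predictor is excluded at that penalty.  Log-likelihoods are
    totals (not means) for information-criterion use.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    XC = np.ascontiguousarray(X.T)
    return _path_kernel(XC, y, lambdas, tol, max_outer, max_inner)
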