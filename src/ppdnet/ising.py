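"""Ising symptom-network estimation (eLasso) and network comparison.

Depressive-symptom items scored 0-3 are binarized (0 = absent, 1-3 =
present) and the joint presence/absence distribution is modelled as a
pairwise Ising Markov random field with node thresholds tau (log-odds of
presence with all neighbours absent) and symmetric couplings omega.

Estimation follows the eLasso recipe: each node is regressed on the
remaining nodes by L1-penalized logistic regression over a descending
penalty path, the penalty is chosen per node by the extended BIC, and
the directed coefficient pairs are symmetrized (AND rule by default:
an edge survives only if both directions are selected, with the mean of
the two coefficients as its weight).

Two estimated networks are compared by a permutation test on the maximum
absolute edge difference (M) and the global-strength difference (S),
re-estimating both networks under each relabelling of the pooled rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from ._glm import lambda_path, logistic_lasso_path

__all__ = [
    "BinaryItemMatrix",
    "IsingNetwork",
    "NctResult",
    "binarize_items",
    "fit_elasso",
    "strength_centrality",
    "global_strength",
    "network_comparison_test",
]


@dataclass
class BinaryItemMatrix:
    """n x p matrix of symptom presence indicators."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("item matrix must be 2-dimensional")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary item matrix may contain only 0 and 1")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class IsingNetwork:
    """Thresholds and symmetric couplings of a binary symptom network."""

    thresholds: np.ndarray
    weights: np.ndarray
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        p = self.thresholds.shape[0]
        if self.weights.shape != (p, p):
            raise ValueError("weights must be p x p")
        if not np.allclose(self.weights, self.weights.T, atol=0, rtol=0):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weights must have a zero diagonal")
        if len(self.labels) != p:
            raise ValueError("label count does not match dimension")

    @property
    def p(self) -> int:
        return self.thresholds.shape[0]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a in range(self.p):
            for b in range(a + 1, self.p):
                if self.weights[a, b] != 0.0:
                    rows.append((self.labels[a], self.labels[b],
                                 self.weights[a, b]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


@dataclass
class NctResult:
    m_observed: float
    s_observed: float
    p_m: float
    p_s: float
    n_perm: int
    seed: int
    m_null: np.ndarray
    s_null: np.ndarray


def binarize_items(item_table: pd.DataFrame) -> BinaryItemMatrix:
    """Collapse ordinal item scores 0-3 to presence indicators.

    A score of 0 codes an absent symptom; scores 1-3 all code a present
    symptom.
    """
    cols = [c for c in item_table.columns if c != "subject_id"]
    values = item_table[cols].to_numpy()
    bad = ~np.isin(values, (0, 1, 2, 3))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"item score out of range at row {r}, column {cols[c]}: "
            f"{values[r, c]!r}")
    return BinaryItemMatrix((values > 0).astype(np.float64), list(cols))


def _ebic_select(loglik: np.ndarray, n_nonzero: np.ndarray, n: int, p: int,
                 gamma: float) -> int:
    """Index of the penalty minimizing the extended BIC for one node."""
    ebic = (-2.0 * loglik + n_nonzero * np.log(n)
            + 2.0 * gamma * n_nonzero * np.log(p - 1))
    return int(np.argmin(ebic))


def fit_elasso(X: BinaryItemMatrix, gamma: float = 0.25, rule: str = "and",
               n_lambda: int = 100, lambda_min_ratio: float = 0.01,
               tol: float = 1e-7) -> IsingNetwork:
    """Estimate an Ising network by nodewise penalized logistic regression.

    Parameters
    ----------
    X : binary item matrix, at least 20 rows, no constant columns
        (constant columns are dropped with a warning and noted in the
        result metadata; their thresholds are set from the clipped
        marginal rate and they carry no edges).
    gamma : extended-BIC sparsity weight.
    rule : "and" keeps an edge only when both nodewise fits select it;
        "or" keeps it when either does.  Weights are the mean of the two
        directed coefficients (for "or", a missing direction counts as
        its value, zero, in the mean).
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    n, p = X.n, X.p
    if n < 20:
        raise ValueError(f"need at least 20 observations, got {n}")

    col_rates = X.values.mean(axis=0)
    constant = (col_rates == 0.0) | (col_rates == 1.0)
    active = np.flatnonzero(~constant)
    dropped = [X.labels[j] for j in np.flatnonzero(constant)]
    if dropped:
        import warnings

        warnings.warn(
            f"constant columns dropped from Ising fit: {dropped}",
            stacklevel=2)

    directed = np.zeros((p, p))
    tau = np.zeros(p)
    # thresholds for constant nodes from the clipped marginal rate
    clipped = np.clip(col_rates, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    tau[constant] = np.log(clipped[constant] / (1.0 - clipped[constant]))

    for idx, node in enumerate(active):
        others = active[active != node]
        Xo = X.values[:, others]
        y = X.values[:, node]
        lams = lambda_path(Xo, y, n_lambda=n_lambda,
                           min_ratio=lambda_min_ratio)
        intercepts, coefs, logliks = logistic_lasso_path(Xo, y, lams, tol=tol)
        coefs[np.abs(coefs) < 1e-6] = 0.0   # solver dust is not an edge
        nnz = (coefs != 0.0).sum(axis=1)
        best = _ebic_select(logliks, nnz, n, len(active), gamma)
        tau[node] = intercepts[best]
        directed[node, others] = coefs[best]

    if rule == "and":
        both = (directed != 0.0) & (directed.T != 0.0)
        weights = np.where(both, 0.5 * (directed + directed.T), 0.0)
    else:
        either = (directed != 0.0) | (directed.T != 0.0)
        weights = np.where(either, 0.5 * (directed + directed.T), 0.0)
    weights = 0.5 * (weights + weights.T)  # enforce exact symmetry
    np.fill_diagonal(weights, 0.0)

    return IsingNetwork(
        thresholds=tau, weights=weights, labels=list(X.labels),
        meta={"gamma": gamma, "rule": rule, "n_lambda": n_lambda,
              "lambda_min_ratio": lambda_min_ratio, "n": n,
              "dropped_constant": dropped})


def strength_centrality(net: IsingNetwork) -> pd.Series:
    """Strength centrality: sum of absolute incident edge weights.

    The attribute ``core_symptom`` on the returned series names the
    maximal-strength node (ties resolved toward the lower node index).
    """
    strengths = np.abs(net.weights).sum(axis=1)
    out = pd.Series(strengths, index=net.labels, name="strength")
    out.attrs["core_symptom"] = net.labels[int(np.argmax(strengths))]
    return out


def global_strength(net: IsingNetwork) -> float:
    """Sum of absolute edge weights, each edge counted once."""
    return float(np.abs(net.weights[np.triu_indices(net.p, k=1)]).sum())


def _observed_stats(netA: IsingNetwork, netB: IsingNetwork):
    m = float(np.max(np.abs(netA.weights - netB.weights)))
    s = abs(global_strength(netA) - global_strength(netB))
    return m, s


def network_comparison_test(XA: BinaryItemMatrix, XB: BinaryItemMatrix,
                            n_perm: int = 1000, seed: int = 0,
                            gamma: float = 0.25, rule: str = "and",
                            n_lambda: int = 100,
                            lambda_min_ratio: float = 0.01) -> NctResult:
    """Permutation test for differences between two Ising networks.

    Pools the rows of both groups, permutes group labels at fixed group
    sizes, re-estimates both networks per permutation, and reports
    add-one-corrected p-values for the maximum absolute edge difference
    (M) and the absolute global-strength difference (S).
    """
    if XA.labels != XB.labels:
        raise ValueError("both groups must share node labels")
    if XA.n < 20 or XB.n < 20:
        raise ValueError("each group needs at least 20 observations")

    def fit(mat: np.ndarray) -> IsingNetwork:
        return fit_elasso(BinaryItemMatrix(mat, XA.labels), gamma=gamma,
                          rule=rule, n_lambda=n_lambda,
                          lambda_min_ratio=lambda_min_ratio)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns in permuted fits
        netA = fit(XA.values)
        netB = fit(XB.values)
        m_obs, s_obs = _observed_stats(netA, netB)

        pooled = np.vstack([XA.values, XB.values])
        nA = XA.n
        rng = np.random.default_rng(seed)
        m_null = np.empty(n_perm)
        s_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            pA = fit(pooled[perm[:nA]])
            pB = fit(pooled[perm[nA:]])
            m_null[b], s_null[b] = _observed_stats(pA, pB)

    p_m = (1.0 + np.sum(m_null >= m_obs)) / (1.0 + n_perm)
    p_s = (1.0 + np.sum(s_null >= s_obs)) / (1.0 + n_perm)
    return NctResult(m_observed=m_obs, s_observed=s_obs, p_m=float(p_m),
                     p_s=float(p_s), n_perm=n_perm, seed=seed,
                     m_null=m_null, s_null=s_null)
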