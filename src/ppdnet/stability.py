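"""Case-dropping bootstrap stability of strength centrality.

For each proportion on a drop grid, random subsets of cases are removed,
the Ising network is re-estimated on the remaining rows, and the
strength order is compared with the full-sample strengths by
correlation.  The CS coefficient is the largest drop proportion at
which at least 95% of the bootstrap correlations stay above 0.7;
values above 0.25 are conventionally called acceptable and above 0.5
good.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ising import BinaryItemMatrix, fit_elasso, strength_centrality

__all__ = ["StabilityResult", "case_drop_bootstrap", "cs_coefficient"]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.1, 0.75, 0.1), 2))


@dataclass
class StabilityResult:
    table: pd.DataFrame       # proportion, boot, correlation (NaN = failed)
    proportions: tuple
    n_boot: int
    seed: int
    full_strength: pd.Series
    n_failed: int


def _correlate(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a = pd.Series(a).rank().to_numpy()
        b = pd.Series(b).rank().to_numpy()
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(X: BinaryItemMatrix,
                        proportions=DEFAULT_PROPORTIONS,
                        n_boot: int = 250, seed: int = 0,
                        method: str = "pearson",
                        **fit_kwargs) -> StabilityResult:
    """Correlation of subset strengths with full-sample strengths.

    Subsets are drawn without replacement.  Subset fits that fail, or
    whose strength vector is constant (no edges), contribute a missing
    correlation, which counts against the retention probability in
    :func:`cs_coefficient`.
    """
    proportions = tuple(float(q) for q in proportions)
    if len(proportions) == 0:
        raise ValueError("the drop-proportion grid is empty")
    if any(not 0 < q < 1 for q in proportions):
        raise ValueError("drop proportions must lie in (0, 1)")
    if sorted(proportions) != list(proportions):
        raise ValueError("drop proportions must be increasing")
    n = X.n
    if n * (1 - max(proportions)) < 20:
        raise ValueError("largest drop leaves fewer than 20 cases")

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = strength_centrality(fit_elasso(X, **fit_kwargs))
        rng = np.random.default_rng(seed)
        rows = []
        n_failed = 0
        for q in proportions:
            keep = n - int(round(q * n))
            for b in range(n_boot):
                idx = rng.choice(n, size=keep, replace=False)
                try:
                    net = fit_elasso(
                        BinaryItemMatrix(X.values[idx], X.labels),
                        **fit_kwargs)
                    sub = strength_centrality(net)
                    r = _correlate(sub.to_numpy(), full.to_numpy(), method)
                except ValueError:
                    r = np.nan
                if np.isnan(r):
                    n_failed += 1
                rows.append((q, b, r))
    table = pd.DataFrame(rows, columns=["proportion", "boot", "correlation"])
    return StabilityResult(table=table, proportions=proportions,
                           n_boot=n_boot, seed=seed, full_strength=full,
                           n_failed=n_failed)


def cs_coefficient(res: StabilityResult, cor_threshold: float = 0.7,
                   prob: float = 0.95) -> float:
    """Largest drop proportion maintaining correlated centralities.

    The largest grid proportion q such that for every proportion <= q
    the estimated probability of a subset-full correlation >= cor
    threshold is at least ``prob``; 0 if the first grid point already
    fails.  Missing correlations count as failures.
    """
    cs = 0.0
    for q in res.proportions:
        sub = res.table[res.table.proportion == q].correlation
        ok = (sub >= cor_threshold).mean()   # NaN compares False
        if ok >= prob:
            cs = q
        else:
            break
    return cs
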