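"""Lag-based baselines: conditional multivariate Granger causality and a
Yule-Walker MVAR with a permutation test.

Both methods assume a linear, Gaussian, stationary vector time series and
exploit *temporal* precedence — in contrast to FASK/Two-Step, which treat
the records as i.i.d. draws.  At fMRI sampling rates the causal dynamics
are much faster than the acquisition, which is why these baselines degrade
sharply under temporal undersampling.

* :func:`mvgc_search` — full-conditional Granger causality: the VAR lag
  order is chosen by BIC, each ordered pair (X, Y) is tested by the F-test
  of joint nullity of X's lag coefficients in Y's full equation, and
  Benjamini-Hochberg FDR control is applied over all v(v-1) tests.  Both
  directions may survive, yielding 2-cycles.
* :func:`mvarp_search` — lag-1 MVAR coefficients obtained directly from the
  Yule-Walker relation Q1 = A Q0, with each coefficient judged against a
  permutation null built by independently shuffling every column over time
  (destroying all temporal dependence while preserving marginals).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.api import VAR

from .graphs import DirectedGraph

__all__ = ["mvgc_search", "mvarp_search", "yule_walker_var1"]


def mvgc_search(
    data: np.ndarray,
    alpha_fdr: float = 1e-5,
    max_lag: int = 5,
    nodes: list[str] | None = None,
) -> DirectedGraph:
    """Conditional multivariate Granger causality with BH-FDR edge selection.

    Returns a directed graph; an edge X -> Y survives iff the F-test that
    X's lags add nothing to Y's full-conditional regression is rejected
    after FDR correction at `alpha_fdr`.
    """
    data = np.asarray(data, dtype=float)
    n, v = data.shape
    if n < (max_lag + 2) * v:
        raise ValueError("too few observations for the requested max lag")
    names = nodes if nodes is not None else [f"X{i+1}" for i in range(v)]

    model = VAR(data)
    order = model.select_order(maxlags=max_lag)
    p = max(1, int(order.bic))
    res = model.fit(p)

    pairs: list[tuple[str, str]] = []
    pvals: list[float] = []
    for xi in range(v):
        for yi in range(v):
            if xi == yi:
                continue
            test = res.test_causality(caused=yi, causing=xi, kind="f")
            pairs.append((names[xi], names[yi]))
            pvals.append(float(test.pvalue))

    reject, *_ = multipletests(pvals, alpha=alpha_fdr, method="fdr_bh")
    g = DirectedGraph(names)
    for (tail, head), keep in zip(pairs, reject):
        if keep:
            g.add_edge(tail, head)
    return g


def yule_walker_var1(data: np.ndarray) -> np.ndarray:
    """Lag-1 VAR coefficients A = Q1 Q0^{-1} from empirical cross-covariances.

    Q0 = Cov(x_t), Q1 = Cov(x_{t+1}, x_t); A[i, j] is the lag-1 effect of
    variable j on variable i.
    """
    X = np.asarray(data, dtype=float)
    X = X - X.mean(axis=0)
    n = X.shape[0]
    Q0 = X[:-1].T @ X[:-1] / (n - 1)
    Q1 = X[1:].T @ X[:-1] / (n - 1)
    try:
        return Q1 @ np.linalg.inv(Q0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular lag-0 covariance Q0") from exc


def mvarp_search(
    data: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 1e-3,
    nodes: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> DirectedGraph:
    """Yule-Walker MVAR with a two-sided permutation test per coefficient.

    The null distribution of each A_ij comes from `n_permutations` datasets
    in which every column is independently permuted over time; j -> i is
    kept iff the observed A_ij falls outside the two-sided (1 - alpha)
    empirical null band.  The diagonal (self-lag) is ignored for the graph.
    """
    data = np.asarray(data, dtype=float)
    n, v = data.shape
    if n < 10 * v:
        raise ValueError("sample too small: need at least 10 records per variable")
    names = nodes if nodes is not None else [f"X{i+1}" for i in range(v)]
    rng = np.random.default_rng(rng)

    A_obs = yule_walker_var1(data)
    null = np.empty((n_permutations, v, v))
    perm = data.copy()
    for b in range(n_permutations):
        for j in range(v):
            perm[:, j] = data[rng.permutation(n), j]
        null[b] = yule_walker_var1(perm)

    lo = np.quantile(null, alpha / 2.0, axis=0)
    hi = np.quantile(null, 1.0 - alpha / 2.0, axis=0)
    g = DirectedGraph(names)
    for i in range(v):
        for j in range(v):
            if i == j:
                continue
            if A_obs[i, j] < lo[i, j] or A_obs[i, j] > hi[i, j]:
                g.add_edge(names[j], names[i])
    return g
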