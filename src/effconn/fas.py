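"""FAS-stable: order-independent adjacency search with BIC-scored CI tests.

The skeleton phase of the PC-stable family: starting from the complete
undirected graph, edges are removed whenever a conditional-independence
fact is found, with conditioning sets of increasing size drawn from
neighbor sets that are *frozen* at the start of each depth — which makes
the output invariant to the ordering of the data columns.

Conditional independence X _||_ Y | S is decided by comparing penalized
Gaussian-likelihood scores of the two nested linear regressions X <- S and
X <- {Y} u S:

    BIC* = -2 ln(ML) + c * k * ln(n)

where k counts the regression covariates, n the sample size and c >= 1 is a
*penalty discount* that forces extra sparsity; c = 1 recovers the ordinary
BIC.  Independence is concluded iff the smaller model scores strictly
better (ties conservatively keep the edge).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .graphs import DirectedGraph

__all__ = ["CITestConfig", "bic_star_ci_test", "fas_stable_search"]


@dataclass
class CITestConfig:
    """Penalty discount and conditioning-depth cap for the CI oracle."""

    penalty_discount: float = 2.0
    max_depth: int | None = None  # None = unlimited

    def __post_init__(self) -> None:
        if self.penalty_discount < 0:
            raise ValueError("penalty discount must be nonnegative")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max depth must be nonnegative")


def _rss(y: np.ndarray, X: np.ndarray, names: tuple[str, ...]) -> float:
    """Residual sum of squares of y on [1, X]; raises on collinearity."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design matrix for conditioning set {names}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def bic_star_ci_test(
    data: np.ndarray,
    x: int,
    y: int,
    S: tuple[int, ...] = (),
    c: float = 2.0,
) -> tuple[bool, float, float]:
    """Decide X _||_ Y | S by nested-regression BIC* comparison.

    Returns ``(independent, score_small, score_big)``.  The Gaussian
    log-likelihood enters through its residual-variance form,
    -2 ln(ML) = n ln(RSS/n) up to a constant that cancels in the
    comparison; k counts covariates only (the intercept is unpenalized).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n <= len(S) + 2:
        raise ValueError("sample size too small for this conditioning set")
    yv = data[:, x]
    Xs = data[:, list(S)] if S else np.empty((n, 0))
    Xb = data[:, list(S) + [y]]
    rss_small = _rss(yv, Xs, tuple(str(s) for s in S))
    rss_big = _rss(yv, Xb, tuple(str(s) for s in S) + (str(y),))
    score_small = n * np.log(max(rss_small, 1e-300) / n) + c * len(S) * np.log(n)
    score_big = n * np.log(max(rss_big, 1e-300) / n) + c * (len(S) + 1) * np.log(n)
    return bool(score_small < score_big), score_small, score_big


def fas_stable_search(
    data: np.ndarray,
    config: CITestConfig | None = None,
    nodes: list[str] | None = None,
) -> DirectedGraph:
    """Estimate the undirected skeleton of the data-generating graph.

    Returns a :class:`DirectedGraph` holding each undirected adjacency as a
    pair of directed edges (the ``A -- B`` dialect of the edge-list format
    writes them back as undirected lines).
    """
    config = config or CITestConfig()
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("data contains missing values")
    n, v = data.shape
    names = nodes if nodes is not None else [f"X{i+1}" for i in range(v)]
    c = config.penalty_discount

    adj: dict[int, set[int]] = {i: set(range(v)) - {i} for i in range(v)}

    depth = 0
    while True:
        if config.max_depth is not None and depth > config.max_depth:
            break
        frozen = {i: sorted(adj[i]) for i in range(v)}  # order-independence
        if all(len(frozen[i]) - 1 < depth for i in range(v)):
            break
        for i in range(v):
            for j in range(i + 1, v):
                if j not in adj[i]:
                    continue
                removed = False
                for base in (i, j):
                    other = j if base == i else i
                    pool = [k for k in frozen[base] if k != other]
                    if len(pool) < depth:
                        continue
                    for S in combinations(pool, depth):
                        indep, *_ = bic_star_ci_test(data, base, other, S, c)
                        if indep:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            removed = True
                            break
                    if removed:
                        break
        depth += 1

    g = DirectedGraph(names)
    for i in range(v):
        for j in adj[i]:
            g.add_edge(names[i], names[j])
    return g
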