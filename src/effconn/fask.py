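"""FASK: Fast Adjacency Skewness search for cyclic graphs.

FASK runs FAS-stable to obtain undirected adjacencies and then decides, for
every adjacent pair X - Y, between X -> Y, X <- Y and the 2-cycle X <=> Y
using conditional second moments computed on the positive half-samples of
centered data.  The information exploited is the *skewness* of the BOLD
signal: for skewed variables, corr(X, Y | X > 0) and corr(X, Y | Y > 0)
react asymmetrically to the causal direction.

* **2-cycle test** — X <=> Y is declared when corr(X,Y) differs
  significantly from *both* corr(X,Y | X>0) and corr(X,Y | Y>0);
* **left-right rule** — otherwise X -> Y iff

      E(XY|X>0)/sqrt(E(X^2|X>0) E(Y^2|X>0))
    - E(XY|Y>0)/sqrt(E(X^2|Y>0) E(Y^2|Y>0)) > 0;

* **fallback** — a 2-cycle with near-cancelling opposite-sign coefficients
  can look marginally independent and be missed by FAS-stable, so every
  *non*-adjacent pair whose two conditional correlations differ by more
  than `fallback_delta` (default 0.3) is added back and oriented by the
  same rules.

The significance test for a correlation difference is a Fisher-z contrast
with variance 1/(n1-3) + 1/(n2-3); the choice is isolated in
:func:`correlation_difference_pvalue` so an alternative (e.g. bootstrap)
can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .fas import CITestConfig, fas_stable_search
from .graphs import DirectedGraph

__all__ = [
    "FaskConfig",
    "conditional_correlation",
    "correlation_difference_pvalue",
    "twocycle_test",
    "left_right_rule",
    "fask_search",
]

_MIN_SUBSAMPLE = 10


@dataclass
class FaskConfig:
    penalty_discount: float = 2.0
    twocycle_alpha: float = 1e-6
    fallback_delta: float = 0.3
    max_depth: int | None = None
    #: largest conditioning-subset size used inside the 2-cycle test
    twocycle_cond_depth: int = 2
    #: optional sign flip of the left-right statistic for negatively skewed
    #: variables; off by default (the rule is applied literally).
    skew_sign_correction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.twocycle_alpha < 1:
            raise ValueError("twocycle_alpha must be in (0, 1)")
        if self.fallback_delta <= 0:
            raise ValueError("fallback_delta must be positive")


def _pos_subsample(cond: np.ndarray, *cols: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = cond > 0
    if mask.sum() < _MIN_SUBSAMPLE:
        raise ValueError("conditioning subsample has fewer than 10 records")
    return tuple(col[mask] for col in cols)


def conditional_correlation(x: np.ndarray, y: np.ndarray, cond: str = "x") -> float:
    """Pearson corr(X, Y) on the records where the conditioning variable > 0.

    `cond` is ``"x"`` or ``"y"``; the variables are assumed centered, so the
    positive half-sample is the above-mean half.
    """
    cvar = x if cond == "x" else y
    xs, ys = _pos_subsample(cvar, x, y)
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("degenerate (constant) conditioning subsample")
    return float(np.corrcoef(xs, ys)[0, 1])


def correlation_difference_pvalue(
    r1: float, n1: int, r2: float, n2: int
) -> float:
    """Two-sided p-value for r1 != r2 via the Fisher-z contrast."""
    r1 = min(max(r1, -0.999999), 0.999999)
    r2 = min(max(r2, -0.999999), 0.999999)
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(2.0 * stats.norm.sf(abs(z)))


def _partial_corr(x: np.ndarray, y: np.ndarray, Z: np.ndarray,
                  mask: np.ndarray | None = None) -> float:
    """Partial corr(x, y | Z) on the masked rows (precision-matrix form)."""
    cols = [x, y] + [Z[:, k] for k in range(Z.shape[1])]
    M = np.column_stack(cols)
    if mask is not None:
        M = M[mask]
    C = np.corrcoef(M.T)
    P = np.linalg.inv(C)
    return float(-P[0, 1] / math.sqrt(P[0, 0] * P[1, 1]))


def twocycle_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 1e-6,
    adjacent: np.ndarray | None = None,
    max_cond: int = 2,
) -> bool:
    """Test for direct feedback X <=> Y via conditional-correlation shifts.

    The signature of a 2-cycle is that corr(X, Y) differs significantly
    from *both* corr(X, Y | X > 0) and corr(X, Y | Y > 0).  A shift in only
    one of the two is what a one-directional edge produces, and a shift
    explainable away by other variables is not feedback either: when
    `adjacent` (columns of the other variables adjacent to X or Y) is
    given, the partial-correlation version of the contrast must be
    significant for every conditioning subset of size <= `max_cond` for
    the pair to be declared a 2-cycle.
    """
    if adjacent is None:
        adjacent = np.empty((len(x), 0))
    n_adj = adjacent.shape[1]
    n = len(x)
    mx, my = x > 0, y > 0
    if mx.sum() < _MIN_SUBSAMPLE or my.sum() < _MIN_SUBSAMPLE:
        raise ValueError("conditioning subsample has fewer than 10 records")
    nx, ny = int(mx.sum()), int(my.sum())
    for size in range(min(n_adj, max_cond) + 1):
        for S in combinations(range(n_adj), size):
            Z = adjacent[:, list(S)]
            try:
                r = _partial_corr(x, y, Z)
                rx = _partial_corr(x, y, Z, mx)
                ry = _partial_corr(x, y, Z, my)
            except np.linalg.LinAlgError:
                continue
            p_x = correlation_difference_pvalue(r, n, rx, nx)
            p_y = correlation_difference_pvalue(r, n, ry, ny)
            if not (p_x < alpha and p_y < alpha):
                return False
    return True


def left_right_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """The conditional-moment contrast; positive favours X -> Y."""
    xs, ys = _pos_subsample(x, x, y)
    lhs = np.mean(xs * ys) / math.sqrt(np.mean(xs**2) * np.mean(ys**2))
    xs2, ys2 = _pos_subsample(y, x, y)
    rhs = np.mean(xs2 * ys2) / math.sqrt(np.mean(xs2**2) * np.mean(ys2**2))
    return float(lhs - rhs)


def left_right_rule(
    x: np.ndarray, y: np.ndarray, skew_sign_correction: bool = False
) -> bool:
    """True for the orientation X -> Y, False for X <- Y.

    With `skew_sign_correction`, the statistic is flipped when the product
    of the two sample skewnesses is negative (an optional variant; the
    default applies the rule literally).
    """
    stat = left_right_statistic(x, y)
    if skew_sign_correction:
        sk = stats.skew(x) * stats.skew(y)
        if sk < 0:
            stat = -stat
    return stat > 0


def fask_search(
    data: np.ndarray,
    config: FaskConfig | None = None,
    nodes: list[str] | None = None,
) -> DirectedGraph:
    """Run FASK on a records x variables data matrix.

    Data are column-centered before all conditional-moment computations.
    Every FAS-stable adjacency comes back oriented (as one or both
    directions); the fallback scan may add extra pairs missed by the
    adjacency search.
    """
    config = config or FaskConfig()
    data = np.asarray(data, dtype=float)
    data = data - data.mean(axis=0)
    v = data.shape[1]
    names = nodes if nodes is not None else [f"X{i+1}" for i in range(v)]

    skel = fas_stable_search(
        data, CITestConfig(config.penalty_discount, config.max_depth), names
    )
    adjacent = {frozenset(e) for e in skel.edges}

    g = DirectedGraph(names)

    neighbors = {nm: set() for nm in names}
    for tail, head in skel.edges:
        neighbors[tail].add(head)

    def orient(i: int, j: int) -> None:
        x, y = data[:, i], data[:, j]
        others = sorted(
            (neighbors[names[i]] | neighbors[names[j]]) - {names[i], names[j]}
        )
        Z = data[:, [names.index(o) for o in others]]
        if twocycle_test(x, y, config.twocycle_alpha, Z, config.twocycle_cond_depth):
            g.add_edge(names[i], names[j])
            g.add_edge(names[j], names[i])
        elif left_right_rule(x, y, config.skew_sign_correction):
            g.add_edge(names[i], names[j])
        else:
            g.add_edge(names[j], names[i])

    for i in range(v):
        for j in range(i + 1, v):
            if frozenset((names[i], names[j])) in adjacent:
                orient(i, j)

    # fallback: near-cancelling 2-cycles can defeat the adjacency search
    for i in range(v):
        for j in range(i + 1, v):
            if frozenset((names[i], names[j])) in adjacent:
                continue
            x, y = data[:, i], data[:, j]
            diff = abs(
                conditional_correlation(x, y, "x")
                - conditional_correlation(x, y, "y")
            )
            if diff > config.fallback_delta:
                orient(i, j)

    return g
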