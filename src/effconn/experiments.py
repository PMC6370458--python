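"""Simulation-study harness: batch runs, sensitivity analyses, parameter
tuning, and subsampling-based stability selection.

The canonical protocol: simulate a pool of scanning sessions for a
ground-truth network; per repetition, draw `sessions_per_concat` sessions
without replacement, center each and concatenate, run a search algorithm,
and score the estimated graph against the truth; report metric means and
SDs over repetitions.  Everything is driven by one master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .baselines import mvgc_search, mvarp_search
from .fas import CITestConfig, fas_stable_search
from .fask import FaskConfig, fask_search
from .graphs import DirectedGraph
from .metrics import EvalReport, evaluate_graphs, matthews_correlation
from .networks import WeightedConnectivity
from .simulate import BoldSession, SimulationConfig, concatenate_sessions, make_session
from .twostep import TwoStepConfig, twostep_search

__all__ = [
    "StudyConfig",
    "StudyResult",
    "StabilityConfig",
    "run_study",
    "sensitivity_experiment",
    "tune_parameters",
    "subsample_stability",
    "stability_threshold",
    "ALGORITHMS",
]

SearchFn = Callable[[np.ndarray, list[str]], DirectedGraph]


def _fask(data, nodes, **params):
    return fask_search(data, FaskConfig(**params), nodes)


def _twostep(data, nodes, **params):
    return twostep_search(data, TwoStepConfig(**params), nodes)[1]


def _fas(data, nodes, **params):
    return fas_stable_search(data, CITestConfig(**params), nodes)


def _mvgc(data, nodes, **params):
    return mvgc_search(data, nodes=nodes, **params)


def _mvarp(data, nodes, **params):
    return mvarp_search(data, nodes=nodes, **params)


#: name -> callable(data, nodes, **params) registry used by studies and CLI
ALGORITHMS: dict[str, Callable] = {
    "fask": _fask,
    "twostep": _twostep,
    "fas": _fas,
    "mvgc": _mvgc,
    "mvarp": _mvarp,
}


@dataclass
class StudyConfig:
    """One batch simulation study.

    `network` may be a fixed :class:`WeightedConnectivity` or a factory
    ``rng -> WeightedConnectivity`` drawing a fresh coefficient
    parameterization for every session over a fixed skeleton (the protocol
    for the simulated benchmark conditions, where coefficients are sampled
    per dataset); with a factory, `truth` must name the skeleton graph.
    """

    network: WeightedConnectivity | Callable
    algorithm: str | Callable = "fask"
    params: dict = field(default_factory=dict)
    truth: DirectedGraph | None = None
    n_sessions: int = 60
    sessions_per_concat: int = 10
    n_repetitions: int = 60
    measurement_noise: bool = True
    tr: float = 1.2
    n_timepoints: int = 500
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sessions_per_concat > self.n_sessions:
            raise ValueError("sessions_per_concat cannot exceed n_sessions")
        if callable(self.network) and self.truth is None:
            raise ValueError("a network factory requires an explicit truth graph")

    def truth_graph(self) -> DirectedGraph:
        if self.truth is not None:
            return self.truth
        return self.network.skeleton

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            duration=self.n_timepoints * self.tr, tr=self.tr, **self.sim_overrides
        )


@dataclass
class StudyResult:
    per_repetition: pd.DataFrame  # one row per repetition, metric columns
    n_failures: int

    def mean(self) -> pd.Series:
        return self.per_repetition.mean(numeric_only=True)

    def sd(self) -> pd.Series:
        return self.per_repetition.std(numeric_only=True)


def _resolve(algorithm: str | Callable) -> Callable:
    if callable(algorithm):
        return algorithm
    return ALGORITHMS[algorithm]


def _report_row(report: EvalReport, estimate: DirectedGraph,
                truth: DirectedGraph) -> dict:
    row = dict(report.as_dict())
    row["MCC_orientation"] = matthews_correlation(estimate, truth, "orientation")
    row["MCC_adjacency"] = matthews_correlation(estimate, truth, "adjacency")
    row["n_edges"] = len(estimate.edges)
    return row


def simulate_session_pool(
    config: StudyConfig, rng: np.random.Generator
) -> list[BoldSession]:
    sim = config.simulation_config()
    sessions = []
    for _ in range(config.n_sessions):
        net = config.network(rng) if callable(config.network) else config.network
        sessions.append(make_session(sim, net, rng))
    return sessions


def run_study(
    config: StudyConfig,
    sessions: list[BoldSession] | None = None,
) -> StudyResult:
    """Execute a batch study; returns per-repetition metrics.

    A pre-simulated session pool may be passed to share sessions between
    studies that differ only in the algorithm (as the tuning and
    sensitivity protocols do).  Repetition failures are excluded and
    counted.
    """
    rng = np.random.default_rng(config.seed)
    if sessions is None:
        sessions = simulate_session_pool(config, rng)
    truth = config.truth_graph()
    search = _resolve(config.algorithm)
    rows = []
    failures = 0
    for _ in range(config.n_repetitions):
        chosen = rng.choice(len(sessions), size=config.sessions_per_concat,
                            replace=False)
        mats = [
            sessions[i].y_observed if config.measurement_noise
            else sessions[i].y_clean
            for i in chosen
        ]
        data = concatenate_sessions(mats, mode="center")
        try:
            estimate = search(data, truth.nodes, **config.params)
        except Exception:
            failures += 1
            continue
        rows.append(_report_row(evaluate_graphs(estimate, truth), estimate, truth))
    return StudyResult(pd.DataFrame(rows), failures)


def sensitivity_experiment(
    config: StudyConfig,
    factor: str,
    treatment_value=None,
) -> pd.DataFrame:
    """Percentage change of each metric under one manipulated factor.

    ``factor="noise"`` switches measurement noise off in the treatment;
    ``factor="undersampling"`` raises TR to `treatment_value` (default 3 s)
    while holding the number of datapoints fixed (longer sessions).
    Returns a table with baseline, treatment and %delta = 100 * (treatment -
    baseline) / baseline rows; a zero baseline yields NaN.
    """
    if factor == "noise":
        treatment = replace(config, measurement_noise=False)
    elif factor == "undersampling":
        treatment = replace(config, tr=float(treatment_value or 3.0))
    else:
        raise ValueError(f"unknown factor {factor!r}")

    base = run_study(config).mean()
    treat = run_study(treatment).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (treat - base) / base
    delta[base == 0] = math.nan
    return pd.DataFrame({"baseline": base, "treatment": treat, "pct_change": delta})


def tune_parameters(
    algorithm: str | Callable,
    grid: list[dict],
    training_configs: list[StudyConfig],
    session_pools: list[list[BoldSession]] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Grid search maximizing mean orientation-level Matthews correlation.

    Each grid point is evaluated by running every training study with those
    parameters; precision/recall trade-offs are decided by MCC, and exact
    ties go to the sparsest setting (fewest mean estimated edges).
    Returns (best parameters, per-grid-point summary table).
    """
    if not grid:
        raise ValueError("empty parameter grid")
    records = []
    for point in grid:
        mccs, edges = [], []
        for k, cfg in enumerate(training_configs):
            cfg = replace(cfg, algorithm=algorithm, params=point)
            pool = session_pools[k] if session_pools is not None else None
            res = run_study(cfg, sessions=pool)
            mccs.append(res.mean().get("MCC_orientation", math.nan))
            edges.append(res.mean().get("n_edges", math.nan))
        records.append({**point, "mcc": float(np.mean(mccs)),
                        "n_edges": float(np.mean(edges))})
    table = pd.DataFrame(records)
    ranked = table.sort_values(["mcc", "n_edges"], ascending=[False, True])
    best = ranked.iloc[0]
    best_params = {k: best[k] for k in grid[0]}
    return best_params, table


def simple_study(
    network_id: int,
    variant: str = "amplifying",
    coefficient_regime: str = "test",
    **kwargs,
) -> StudyConfig:
    """StudyConfig for one simple-network condition.

    Coefficients are redrawn per session from the truncated Gaussian of the
    chosen regime ("test": mean 0.5 in [0.3, 0.7]; "training": mean 0.4 in
    [0.2, 0.6], the regime used for parameter tuning).
    """
    from .networks import build_simple_network, simple_network_skeleton

    regimes = {"test": (0.5, 0.1, 0.3, 0.7), "training": (0.4, 0.1, 0.2, 0.6)}
    mean, sd, low, high = regimes[coefficient_regime]

    def factory(rng):
        return build_simple_network(network_id, variant, rng, mean, sd, low, high)

    return StudyConfig(
        network=factory, truth=simple_network_skeleton(network_id), **kwargs
    )


# ---------------------------------------------------------------------------
# Stability selection


@dataclass
class StabilityConfig:
    k: int = 100                # number of subsamples
    fraction: float = 0.5       # subsample size N * fraction, w/o replacement
    threshold: float | None = None  # t in (0.5, 1]; None = tolerated-FP rule
    tolerated_fp: float | None = None  # edges; default 5% of p = v(v-1)

    def __post_init__(self) -> None:
        if self.threshold is not None and not 0.5 < self.threshold <= 1:
            raise ValueError("threshold t must satisfy 0.5 < t <= 1")


def stability_threshold(mean_selected: float, p: int, tolerated_fp: float) -> float:
    """Frequency threshold from the stability-selection error bound.

    With q edges selected per subsample on average, the expected number of
    falsely stable edges among p candidates is bounded by
    q^2 / ((2t - 1) p); solving for t at the tolerated count gives
    t = (1 + q^2 / (p * tolerated)) / 2, clipped into (0.5, 1].
    """
    t = 0.5 * (1.0 + mean_selected**2 / (p * tolerated_fp))
    return min(1.0, max(t, 0.5 + 1e-9))


def subsample_stability(
    data: np.ndarray,
    algorithm: str | Callable,
    params: dict,
    stability: StabilityConfig | None = None,
    nodes: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[DirectedGraph, pd.DataFrame]:
    """Stability selection: run the search on k half-subsamples and keep
    edges appearing in more than a proportion t of them.

    Returns the stable graph and the per-directed-edge frequency table.
    """
    stability = stability or StabilityConfig()
    rng = np.random.default_rng(rng)
    data = np.asarray(data, dtype=float)
    n, v = data.shape
    names = nodes if nodes is not None else [f"X{i+1}" for i in range(v)]
    search = _resolve(algorithm)

    size = int(n * stability.fraction)
    counts: dict[tuple[str, str], int] = {}
    n_selected = []
    failures = 0
    for _ in range(stability.k):
        rows = rng.choice(n, size=size, replace=False)
        try:
            g = search(data[rows], names, **params)
        except Exception:
            failures += 1
            continue
        n_selected.append(len(g.edges))
        for e in g.edges:
            counts[e] = counts.get(e, 0) + 1

    k_eff = stability.k - failures
    p = v * (v - 1)
    if stability.threshold is not None:
        t = stability.threshold
    else:
        tol = stability.tolerated_fp if stability.tolerated_fp is not None else 0.05 * p
        t = stability_threshold(float(np.mean(n_selected or [0])), p, tol)

    freq = pd.DataFrame(
        [(tail, head, c, c / k_eff) for (tail, head), c in sorted(counts.items())],
        columns=["tail", "head", "count", "frequency"],
    )
    stable = DirectedGraph(names)
    for _, row in freq.iterrows():
        if row["frequency"] > t:
            stable.add_edge(row["tail"], row["head"])
    return stable, freq
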