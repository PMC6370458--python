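"""Precision/recall evaluation of estimated directed graphs.

Graphs are scored at three levels:

* **adjacency** — unordered pairs; a 2-cycle counts as one single adjacency;
* **orientation** — ordered pairs; a 2-cycle counts as two distinct directed
  edges, and an edge estimated with the wrong orientation is an orientation
  false positive while the missed true direction is a false negative;
* **2-cycle** — unordered pairs in which both directions are present.

Precision = TP / (TP + FP) and Recall = TP / (TP + FN).  A ratio with zero
denominator is *undefined* and reported as NaN so that averages can exclude
it (e.g. 2-cycle precision for a method that estimated no 2-cycles).

The Matthews correlation coefficient over all possible (un)ordered node
pairs is used for tuning-parameter selection, trading off precision against
recall in a single number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import islice

import networkx as nx

from .graphs import DirectedGraph

__all__ = ["EvalReport", "evaluate_graphs", "matthews_correlation", "cycle_census"]


@dataclass
class EvalReport:
    """Precision/recall at the adjacency, orientation and 2-cycle levels."""

    adjacency_precision: float
    adjacency_recall: float
    orientation_precision: float
    orientation_recall: float
    twocycle_precision: float
    twocycle_recall: float
    twocycle_fp: int
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "AP": self.adjacency_precision,
            "AR": self.adjacency_recall,
            "OP": self.orientation_precision,
            "OR": self.orientation_recall,
            "2CP": self.twocycle_precision,
            "2CR": self.twocycle_recall,
            "2C_FP": self.twocycle_fp,
        }

    def to_tsv(self) -> str:
        """Flat key=value TSV serialization."""
        items = list(self.as_dict().items())
        for level, counts in self.confusion.items():
            items += [(f"{level}_{k}", v) for k, v in counts.items()]
        return "\n".join(f"{k}\t{v}" for k, v in items) + "\n"


def _ratio(tp: int, other: int) -> float:
    denom = tp + other
    return tp / denom if denom else math.nan


def _check_nodes(estimate: DirectedGraph, truth: DirectedGraph) -> None:
    if set(estimate.nodes) != set(truth.nodes):
        raise ValueError("estimate and truth must share the same node set")


def evaluate_graphs(estimate: DirectedGraph, truth: DirectedGraph) -> EvalReport:
    """Score `estimate` against `truth` at all three levels.

    Undefined ratios (0/0) come back as NaN: an empty estimate has undefined
    precisions, and recalls are 0 (or NaN when the truth level is empty too).
    """
    _check_nodes(estimate, truth)

    est_adj, true_adj = estimate.adjacencies(), truth.adjacencies()
    est_dir, true_dir = estimate.edges, truth.edges
    est_2c, true_2c = estimate.two_cycles(), truth.two_cycles()

    confusion = {}
    metrics = {}
    for level, est, true in (
        ("adjacency", est_adj, true_adj),
        ("orientation", est_dir, true_dir),
        ("twocycle", est_2c, true_2c),
    ):
        tp = len(est & true)
        fp = len(est - true)
        fn = len(true - est)
        confusion[level] = {"TP": tp, "FP": fp, "FN": fn}
        metrics[level] = (_ratio(tp, fp), _ratio(tp, fn))

    return EvalReport(
        adjacency_precision=metrics["adjacency"][0],
        adjacency_recall=metrics["adjacency"][1],
        orientation_precision=metrics["orientation"][0],
        orientation_recall=metrics["orientation"][1],
        twocycle_precision=metrics["twocycle"][0],
        twocycle_recall=metrics["twocycle"][1],
        twocycle_fp=confusion["twocycle"]["FP"],
        confusion=confusion,
    )


def matthews_correlation(
    estimate: DirectedGraph, truth: DirectedGraph, level: str = "orientation"
) -> float:
    """MCC of the edge classification over all possible node pairs.

    ``level="orientation"`` classifies all v(v-1) ordered pairs,
    ``level="adjacency"`` all v(v-1)/2 unordered pairs.  Returns 0 when any
    confusion-table marginal is zero (degenerate all-positive/all-negative
    cases).
    """
    _check_nodes(estimate, truth)
    v = len(truth.nodes)
    if level == "orientation":
        est, true = estimate.edges, truth.edges
        total = v * (v - 1)
    elif level == "adjacency":
        est, true = estimate.adjacencies(), truth.adjacencies()
        total = v * (v - 1) // 2
    else:
        raise ValueError(f"unknown level {level!r}")
    tp = len(est & true)
    fp = len(est - true)
    fn = len(true - est)
    tn = total - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def cycle_census(
    net: DirectedGraph, enumerate_limit: int = 100_000
) -> tuple[int, int | None, int | None, float | None]:
    """Count 2-cycles and enumerate simple cycles.

    Returns ``(n_2cycles, n_simple_cycles, max_len, mean_len)``.  2-cycles are
    counted directly from mutual edges.  Simple-cycle enumeration stops once
    `enumerate_limit` cycles have been seen; in that case the last three
    entries are ``None`` (the dense full macaque network is not enumerable).
    """
    n_two = len(net.two_cycles())
    g = net.to_networkx()
    lengths: list[int] = []
    for cyc in islice(nx.simple_cycles(g), enumerate_limit + 1):
        lengths.append(len(cyc))
        if len(lengths) > enumerate_limit:
            return n_two, None, None, None
    if not lengths:
        return n_two, 0, 0, 0.0
    return n_two, len(lengths), max(lengths), sum(lengths) / len(lengths)
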