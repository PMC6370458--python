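"""Precision/recall/MCC evaluation against brute-force confusion oracles."""

import math

import numpy as np
import pytest

from effconn.graphs import DirectedGraph
from effconn.metrics import cycle_census, evaluate_graphs, matthews_correlation


def g(nodes, *edges):
    return DirectedGraph(nodes, edges)


NODES3 = ["X", "Y", "Z"]


class TestEvaluateExamples:
    def test_identity_estimate_scores_one_everywhere(self):
        truth = g(NODES3, ("X", "Y"), ("Y", "Z"), ("Z", "Y"))
        r = evaluate_graphs(truth, truth)
        assert (r.adjacency_precision, r.adjacency_recall) == (1, 1)
        assert (r.orientation_precision, r.orientation_recall) == (1, 1)
        assert (r.twocycle_precision, r.twocycle_recall) == (1, 1)

    def test_mixed_estimate_hand_enumeration(self):
        # truth X->Y, Y<->Z; estimate X->Y, Y->Z, X->Z
        truth = g(NODES3, ("X", "Y"), ("Y", "Z"), ("Z", "Y"))
        est = g(NODES3, ("X", "Y"), ("Y", "Z"), ("X", "Z"))
        r = evaluate_graphs(est, truth)
        assert r.adjacency_precision == pytest.approx(2 / 3)
        assert r.adjacency_recall == 1.0
        assert r.orientation_precision == pytest.approx(2 / 3)
        assert r.orientation_recall == pytest.approx(2 / 3)
        assert math.isnan(r.twocycle_precision)  # no 2-cycles estimated
        assert r.twocycle_recall == 0.0

    def test_extra_edge_beside_true_twocycle(self):
        truth = g(NODES3, ("X", "Y"), ("Y", "X"))
        est = g(NODES3, ("X", "Y"), ("Y", "X"), ("Y", "Z"))
        r = evaluate_graphs(est, truth)
        assert r.adjacency_precision == pytest.approx(1 / 2)
        assert r.adjacency_recall == 1.0
        assert r.orientation_precision == pytest.approx(2 / 3)
        assert r.orientation_recall == 1.0
        assert r.twocycle_precision == 1.0 and r.twocycle_recall == 1.0

    def test_empty_estimate_undefined_precision_zero_recall(self):
        truth = g(NODES3, ("X", "Y"))
        r = evaluate_graphs(g(NODES3), truth)
        assert math.isnan(r.adjacency_precision)
        assert r.adjacency_recall == 0.0
        assert math.isnan(r.twocycle_recall)  # truth has no 2-cycles either

    def test_node_mismatch_raises(self):
        with pytest.raises(ValueError, match="node set"):
            evaluate_graphs(g(["A", "B"]), g(["A", "C"]))


def brute_force_report(est: DirectedGraph, truth: DirectedGraph):
    """Independent oracle: enumerate every ordered/unordered pair."""
    nodes = sorted(truth.nodes)
    counts = {lvl: {"TP": 0, "FP": 0, "FN": 0} for lvl in ("adj", "ori", "two")}
    for a in nodes:
        for b in nodes:
            if a >= b:
                continue
            e_adj = est.has_edge(a, b) or est.has_edge(b, a)
            t_adj = truth.has_edge(a, b) or truth.has_edge(b, a)
            e_two = est.has_edge(a, b) and est.has_edge(b, a)
            t_two = truth.has_edge(a, b) and truth.has_edge(b, a)
            for lvl, e, t in (("adj", e_adj, t_adj), ("two", e_two, t_two)):
                if e and t:
                    counts[lvl]["TP"] += 1
                elif e:
                    counts[lvl]["FP"] += 1
                elif t:
                    counts[lvl]["FN"] += 1
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            e, t = est.has_edge(a, b), truth.has_edge(a, b)
            if e and t:
                counts["ori"]["TP"] += 1
            elif e:
                counts["ori"]["FP"] += 1
            elif t:
                counts["ori"]["FN"] += 1

    def pr(c):
        p = c["TP"] / (c["TP"] + c["FP"]) if c["TP"] + c["FP"] else math.nan
        r = c["TP"] / (c["TP"] + c["FN"]) if c["TP"] + c["FN"] else math.nan
        return p, r

    return {lvl: pr(c) for lvl, c in counts.items()}


def random_graph(rng, nodes, p=0.3):
    gg = DirectedGraph(nodes)
    for a in nodes:
        for b in nodes:
            if a != b and rng.random() < p:
                gg.add_edge(a, b)
    return gg


@pytest.mark.parametrize("seed", range(30))
def test_oracle_equivalence_random_graphs(seed):
    """All six metrics agree with brute-force pair enumeration on random
    graphs over <= 5 nodes."""
    rng = np.random.default_rng(seed)
    nodes = [f"N{i}" for i in range(int(rng.integers(2, 6)))]
    est, truth = random_graph(rng, nodes), random_graph(rng, nodes)
    r = evaluate_graphs(est, truth)
    oracle = brute_force_report(est, truth)
    for got, want in [
        ((r.adjacency_precision, r.adjacency_recall), oracle["adj"]),
        ((r.orientation_precision, r.orientation_recall), oracle["ori"]),
        ((r.twocycle_precision, r.twocycle_recall), oracle["two"]),
    ]:
        for gv, wv in zip(got, want):
            assert (math.isnan(gv) and math.isnan(wv)) or gv == pytest.approx(wv)


@pytest.mark.parametrize("seed", range(10))
def test_relabeling_invariance(seed):
    """Consistently renaming nodes in both graphs leaves all metrics equal."""
    rng = np.random.default_rng(seed)
    nodes = ["A", "B", "C", "D"]
    est, truth = random_graph(rng, nodes), random_graph(rng, nodes)
    mapping = dict(zip(nodes, ["P", "Q", "R", "S"]))

    def relabel(gg):
        return DirectedGraph(
            [mapping[n] for n in gg.nodes],
            [(mapping[a], mapping[b]) for a, b in gg.edges],
        )

    r1 = evaluate_graphs(est, truth).as_dict()
    r2 = evaluate_graphs(relabel(est), relabel(truth)).as_dict()
    for k in r1:
        assert (r1[k] == pytest.approx(r2[k])) or (
            math.isnan(r1[k]) and math.isnan(r2[k])
        )


@pytest.mark.parametrize("seed", range(10))
def test_superset_estimate_has_full_recall(seed):
    """Whenever the estimate contains every true edge, adjacency and
    2-cycle recall are 1 (or undefined if truth has none)."""
    rng = np.random.default_rng(seed)
    nodes = ["A", "B", "C", "D"]
    truth = random_graph(rng, nodes, 0.25)
    est = DirectedGraph(nodes, truth.edges)
    for a in nodes:
        for b in nodes:
            if a != b and rng.random() < 0.3:
                est.add_edge(a, b)
    r = evaluate_graphs(est, truth)
    if truth.edges:
        assert r.adjacency_recall == 1.0
    if truth.two_cycles():
        assert r.twocycle_recall == 1.0


class TestMatthewsCorrelation:
    def test_perfect_estimate(self):
        truth = g(NODES3, ("X", "Y"), ("Y", "Z"))
        assert matthews_correlation(truth, truth) == pytest.approx(1.0)

    def test_complement_estimate(self):
        nodes = ["A", "B", "C"]
        truth = g(nodes, ("A", "B"), ("B", "C"))
        comp = DirectedGraph(nodes)
        for a in nodes:
            for b in nodes:
                if a != b and not truth.has_edge(a, b):
                    comp.add_edge(a, b)
        assert matthews_correlation(comp, truth) == pytest.approx(-1.0)

    def test_direct_formula_three_nodes(self):
        # TP=1 FP=1 FN=0 TN=4 over the 6 ordered pairs
        truth = g(NODES3, ("X", "Y"))
        est = g(NODES3, ("X", "Y"), ("Y", "Z"))
        want = (1 * 4 - 1 * 0) / math.sqrt(2 * 1 * 5 * 4)
        assert matthews_correlation(est, truth) == pytest.approx(want)

    def test_degenerate_marginal_returns_zero(self):
        truth = g(NODES3)
        assert matthews_correlation(g(NODES3), truth) == 0.0


class TestCycleCensus:
    def test_three_ring(self):
        ring = g(NODES3, ("X", "Y"), ("Y", "Z"), ("Z", "X"))
        assert cycle_census(ring) == (0, 1, 3, 3.0)

    def test_two_two_cycles(self):
        gg = g(NODES3, ("X", "Y"), ("Y", "X"), ("Y", "Z"), ("Z", "Y"))
        assert cycle_census(gg) == (2, 2, 2, 2.0)

    def test_enumeration_limit_reports_not_computed(self):
        nodes = [f"N{i}" for i in range(8)]
        full = DirectedGraph(
            nodes, [(a, b) for a in nodes for b in nodes if a != b]
        )
        n2, n_cycles, mx, mean = cycle_census(full, enumerate_limit=50)
        assert n2 == 8 * 7 // 2
        assert n_cycles is None and mx is None and mean is None
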