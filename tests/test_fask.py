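"""FASK: conditional correlations, 2-cycle detection, left-right rule."""

import numpy as np
import pytest

from conftest import make_skewed_pair
from effconn.fask import (
    FaskConfig,
    conditional_correlation,
    fask_search,
    left_right_rule,
    left_right_statistic,
    twocycle_test,
)
from effconn.metrics import evaluate_graphs
from effconn.simulate import concatenate_sessions


class TestConditionalCorrelation:
    def test_identical_variables_give_one(self):
        x = np.random.default_rng(0).normal(0, 1, 1000)
        assert conditional_correlation(x, x.copy(), "x") == pytest.approx(1.0)
        assert conditional_correlation(x, x.copy(), "y") == pytest.approx(1.0)

    def test_gaussian_conditioning_symmetric(self):
        """For a symmetric Gaussian pair the two conditionings agree."""
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200000)
        y = 0.5 * x + rng.normal(0, 1, 200000) * np.sqrt(0.75)
        rx = conditional_correlation(x, y, "x")
        ry = conditional_correlation(x, y, "y")
        assert rx == pytest.approx(ry, abs=0.01)

    def test_skewed_pair_conditioning_asymmetric(self):
        """With skewed cause and noise, the two conditional correlations
        differ systematically (checked against a large-n run)."""
        diffs = [
            conditional_correlation(*make_skewed_pair(s, 20000), "x")
            - conditional_correlation(*make_skewed_pair(s, 20000), "y")
            for s in range(5)
        ]
        assert all(d > 0.02 for d in diffs)

    def test_small_subsample_rejected(self):
        x = -np.ones(100)
        x[:5] = 1.0
        with pytest.raises(ValueError, match="10 records"):
            conditional_correlation(x, x.copy(), "x")


class TestTwoCycleTest:
    def test_gaussian_null_not_flagged(self):
        """Unconnected Gaussian variables are not declared 2-cycles.

        (On *correlated* symmetric-Gaussian pairs the conditional
        correlations attenuate on both half-samples, so the contrast is
        uninformative — skewness is a stated prerequisite of the method;
        see the skewed one-directional case below.)"""
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 5000)
            y = rng.normal(0, 1, 5000)
            x, y = x - x.mean(), y - y.mean()
            hits += twocycle_test(x, y, 1e-6)
        assert hits <= 1

    def test_skewed_one_directional_not_flagged(self):
        hits = 0
        for seed in range(25):
            x, y = make_skewed_pair(seed)
            hits += twocycle_test(x, y, 1e-6)
        assert hits <= 1

    def test_simulated_two_cycle_flagged(self, network5_pool):
        """The X <=> Y pair of the simulated 2-cycle network is detected."""
        D = concatenate_sessions([s.y_observed for s in network5_pool])
        D -= D.mean(axis=0)
        nodes = network5_pool[0].nodes
        x = D[:, nodes.index("X")]
        y = D[:, nodes.index("Y")]
        assert twocycle_test(x, y, 1e-6)


class TestLeftRight:
    def test_antisymmetry(self):
        """Swapping the arguments negates the statistic and reverses the
        decision."""
        for seed in range(10):
            x, y = make_skewed_pair(seed, 2000)
            assert left_right_statistic(x, y) == pytest.approx(
                -left_right_statistic(y, x)
            )
            assert left_right_rule(x, y) != left_right_rule(y, x)

    def test_orientation_accuracy_on_skewed_pairs(self):
        """>= 95% correct direction at n = 5000 on linear non-Gaussian
        pairs generated as x -> y."""
        correct = sum(left_right_rule(*make_skewed_pair(s)) for s in range(40))
        assert correct >= 38

    def test_fixed_fixture_matches_hand_computation(self):
        """The statistic on a printed 20-row fixture equals an independent
        spreadsheet-style evaluation of the conditional moments."""
        x = np.array([1.5, -0.3, 0.8, -1.2, 2.1, 0.4, -0.7, 1.9, -0.2, 0.6,
                      -1.5, 0.9, 2.4, -0.8, 0.3, 1.1, -0.4, 0.7, -1.0, 1.3])
        y = np.array([0.9, -0.1, 0.5, -0.9, 1.6, 0.1, -0.6, 1.2, 0.2, 0.3,
                      -1.1, 0.7, 1.9, -0.5, 0.1, 0.8, -0.3, 0.6, -0.7, 1.0])
        # independent arithmetic: explicit sums over the two half-samples
        px = x > 0
        lhs_num = sum(a * b for a, b in zip(x[px], y[px])) / px.sum()
        lhs_den = np.sqrt(
            (sum(a * a for a in x[px]) / px.sum())
            * (sum(b * b for b in y[px]) / px.sum())
        )
        py = y > 0
        rhs_num = sum(a * b for a, b in zip(x[py], y[py])) / py.sum()
        rhs_den = np.sqrt(
            (sum(a * a for a in x[py]) / py.sum())
            * (sum(b * b for b in y[py]) / py.sum())
        )
        want = lhs_num / lhs_den - rhs_num / rhs_den
        assert left_right_statistic(x, y) == pytest.approx(want, rel=1e-12)


class TestFaskSearch:
    def test_pure_noise_gives_empty_graph(self):
        rng = np.random.default_rng(0)
        D = rng.normal(0, 1, (3000, 4))
        g = fask_search(D, FaskConfig())
        assert not g.edges

    def test_every_adjacency_oriented(self, network5_pool):
        """No FAS adjacency is dropped: each one appears with at least one
        direction in the output."""
        from effconn.fas import CITestConfig, fas_stable_search

        D = concatenate_sessions([s.y_observed for s in network5_pool])
        nodes = network5_pool[0].nodes
        skel = fas_stable_search(D - D.mean(0), CITestConfig(2.0), nodes)
        g = fask_search(D, FaskConfig(), nodes)
        assert skel.adjacencies() <= g.adjacencies()

    def test_column_order_invariance(self, network5_pool):
        D = concatenate_sessions([s.y_observed for s in network5_pool])
        nodes = network5_pool[0].nodes
        g1 = fask_search(D, FaskConfig(), nodes)
        perm = [3, 1, 4, 0, 2]
        g2 = fask_search(D[:, perm], FaskConfig(), [nodes[i] for i in perm])
        assert g1.edges == g2.edges

    def test_recovers_network5_structure(self, network5_pool):
        """On concatenated simulated sessions, FASK finds the 2-cycle and
        all true edges of the two-feeder 2-cycle network."""
        D = concatenate_sessions([s.y_observed for s in network5_pool])
        truth = None
        from effconn import simple_network_skeleton

        truth = simple_network_skeleton(5)
        g = fask_search(D, FaskConfig(), network5_pool[0].nodes)
        r = evaluate_graphs(g, truth)
        assert r.orientation_recall == 1.0
        assert r.twocycle_recall == 1.0
        assert r.twocycle_fp == 0

    def test_fallback_adds_cancelling_two_cycle(self):
        """A 2-cycle with near-cancelling opposite-sign coefficients can be
        marginally near-independent; the fallback re-adds the pair when the
        conditional correlations differ by more than the threshold."""
        rng = np.random.default_rng(8)
        n = 20000
        e1 = rng.exponential(1, n) - 1
        e2 = rng.exponential(1, n) - 1
        B = np.array([[0.0, -0.65], [0.65, 0.0]])
        X = np.linalg.solve(np.eye(2) - B, np.vstack([e1, e2])).T
        r = abs(np.corrcoef(X[:, 0], X[:, 1])[0, 1])
        cx = conditional_correlation(X[:, 0] - X[:, 0].mean(),
                                     X[:, 1] - X[:, 1].mean(), "x")
        cy = conditional_correlation(X[:, 0] - X[:, 0].mean(),
                                     X[:, 1] - X[:, 1].mean(), "y")
        # the construction really is marginally weak but conditionally split
        assert r < 0.25 and abs(cx - cy) > 0.3
        g = fask_search(X, FaskConfig(), ["X", "Y"])
        assert g.adjacencies() == {frozenset(("X", "Y"))}
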