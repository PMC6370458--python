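"""BOLD simulator: inputs, neuronal integration, balloon model, sessions."""

import numpy as np
import pytest

from effconn import build_simple_network
from effconn.networks import WeightedConnectivity
from effconn.simulate import (
    BalloonParams,
    SimulationConfig,
    balloon_bold,
    concatenate_sessions,
    highpass_runline,
    integrate_neuronal,
    make_session,
    simulate_inputs,
    spectral_exponent,
)


class TestInputs:
    def test_sojourn_means_converge(self):
        """Empirical up/down sojourns approach 2.5 s and 10 s."""
        u = simulate_inputs(1, 40000.0, 0.01, rng=0)[:, 0]
        flips = np.flatnonzero(np.diff(u) != 0) + 1
        runs = np.diff(np.concatenate([[0], flips, [len(u)]])) * 0.01
        states = [u[0] > 0]
        for _ in runs[1:]:
            states.append(not states[-1])
        ups = runs[np.array(states)][1:-1]
        downs = runs[~np.array(states)][1:-1]
        assert ups.mean() == pytest.approx(2.5, rel=0.1)
        assert downs.mean() == pytest.approx(10.0, rel=0.1)

    def test_fraction_of_time_up(self):
        """Renewal ratio of means: 2.5 / 12.5 = 0.2."""
        u = simulate_inputs(3, 40000.0, 0.01, rng=1, amplitude=1.0)
        assert (u > 0).mean() == pytest.approx(0.2, abs=0.02)

    def test_degenerate_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_inputs(1, 0.001, 0.005)

    def test_amplitude_applied(self):
        u = simulate_inputs(1, 100.0, 0.01, rng=2, amplitude=3.5)
        assert set(np.unique(u)) == {0.0, 3.5}


class TestNeuronal:
    def test_impulse_decays_geometrically(self):
        """For A = -I the Euler recursion contracts by (1 - sigma*dt)."""
        net = WeightedConnectivity(["a"], -np.eye(1))
        dt, sigma = 0.005, 10.0
        u = np.zeros((200, 1))
        u[0] = 1.0
        z = integrate_neuronal(net, sigma, u, dt)
        # z[1] = dt*u0; z[t+1] = (1 - sigma dt) z[t] afterwards
        expected = dt * (1 - sigma * dt) ** np.arange(199)
        np.testing.assert_allclose(z[1:, 0], expected, rtol=1e-10)

    def test_unstable_network_rejected_upfront(self):
        A = np.array([[-1.0, 2.0], [2.0, -1.0]])
        net = WeightedConnectivity(["a", "b"], A)
        with pytest.raises(ValueError, match="unstable"):
            integrate_neuronal(net, 10.0, np.zeros((10, 2)), 0.005)

    def test_richardson_step_halving_agreement(self):
        """Trajectories at dt and dt/2 agree to first order."""
        rng = np.random.default_rng(0)
        net = build_simple_network(1, "amplifying", rng)
        u1 = simulate_inputs(5, 20.0, 0.01, rng=3)
        u2 = np.repeat(u1, 2, axis=0)
        z1 = integrate_neuronal(net, 13.2, u1, 0.01)
        z2 = integrate_neuronal(net, 13.2, u2, 0.005)
        err = np.abs(z1 - z2[::2]).max()
        assert err < 0.05 * max(np.abs(z1).max(), 1e-12)

    def test_spectral_exponent_near_power_law(self):
        """Log-log spectrum of z is near-linear with exponent ~ 2.4 over
        the corner-frequency band."""
        rng = np.random.default_rng(4)
        net = build_simple_network(1, "amplifying", rng)
        u = simulate_inputs(5, 300.0, 0.005, rng, amplitude=1.0)
        z = integrate_neuronal(net, 13.2, u, 0.005)
        assert 1.8 < spectral_exponent(z) < 3.0


class TestBalloon:
    def test_zero_input_stays_at_baseline(self):
        y = balloon_bold(np.zeros((2000, 2)), BalloonParams(), 0.005)
        assert np.abs(y).max() < 1e-9

    def test_impulse_response_shape(self):
        """Single-peaked response, peak latency 3-7 s, post-peak undershoot."""
        z = np.zeros((4000, 1))
        z[:100] = 0.3
        y = balloon_bold(z, BalloonParams(), 0.005)[:, 0]
        peak = int(np.argmax(y))
        assert 3.0 < peak * 0.005 < 7.0
        assert y.min() < -0.05 * y.max()  # undershoot
        assert y[peak] > 0

    def test_nonfinite_input_rejected(self):
        z = np.full((10, 1), np.nan)
        with pytest.raises(ValueError):
            balloon_bold(z, BalloonParams(), 0.005)

    def test_transit_time_shifts_latency(self):
        z = np.zeros((4000, 1))
        z[:100] = 0.3
        lat = []
        for tau in (0.7, 1.3):
            y = balloon_bold(z, BalloonParams(), 0.005, np.array([tau]))
            lat.append(np.argmax(y[:, 0]))
        assert lat[0] < lat[1]


class TestSessions:
    @pytest.mark.parametrize("duration,tr", [(600.0, 1.2), (1500.0, 3.0)])
    def test_500_timepoints(self, duration, tr):
        rng = np.random.default_rng(0)
        net = build_simple_network(1, "amplifying", rng)
        s = make_session(SimulationConfig(duration=duration, tr=tr), net, rng)
        assert s.n_timepoints == 500

    def test_measurement_noise_sd(self):
        rng = np.random.default_rng(1)
        net = build_simple_network(1, "amplifying", rng)
        s = make_session(SimulationConfig(), net, rng)
        resid = s.y_observed - s.y_clean
        assert resid.std() == pytest.approx(1.0, rel=0.1)

    def test_bit_reproducible_given_seed(self):
        net = build_simple_network(1, "amplifying", rng_seed=3)
        a = make_session(SimulationConfig(), net, rng=42)
        b = make_session(SimulationConfig(), net, rng=42)
        np.testing.assert_array_equal(a.y_observed, b.y_observed)
        assert a.provenance == b.provenance

    def test_invalid_tr_duration_combo(self):
        with pytest.raises(ValueError, match="integral"):
            SimulationConfig(duration=601.0, tr=1.2)


class TestHighpass:
    def test_removes_slow_trend_keeps_fast(self):
        t = np.arange(500) * 1.2
        slow = np.sin(2 * np.pi * t / 400.0)
        fast = np.sin(2 * np.pi * t / 20.0)
        filtered = highpass_runline((slow + fast)[:, None], 200.0 / (2 * 1.2))[:, 0]
        gain_slow = (filtered @ slow) / (slow @ slow)
        gain_fast = (filtered @ fast) / (fast @ fast)
        assert gain_slow < 0.6  # 400-s component strongly attenuated
        assert gain_fast > 0.95  # 20-s component passes essentially intact


class TestConcatenation:
    def test_row_count_and_zero_means(self):
        rng = np.random.default_rng(0)
        mats = [rng.normal(5.0, 1.0, (50, 3)) for _ in range(4)]
        out = concatenate_sessions(mats, "center")
        assert out.shape == (200, 3)
        np.testing.assert_allclose(out[:50].mean(axis=0), 0, atol=1e-12)

    def test_centering_removes_mean_shift_covariance(self):
        """Two sessions with zero within-session covariance but different
        means have zero covariance after centered concatenation."""
        rng = np.random.default_rng(1)
        s1 = rng.normal(0, 1, (500, 2))
        s2 = rng.normal(0, 1, (500, 2)) + np.array([5.0, 5.0])
        for s in (s1, s2):  # enforce exact zero within-session covariance
            c0 = s[:, 0] - s[:, 0].mean()
            c1 = s[:, 1] - s[:, 1].mean()
            s[:, 1] -= c0 * (c0 @ c1) / (c0 @ c0)
        out = concatenate_sessions([s1, s2], "center")
        assert abs(np.cov(out.T)[0, 1]) < 1e-10
        raw = np.vstack([s1, s2])
        assert abs(np.cov(raw.T)[0, 1]) > 1.0  # without centering it is large

    def test_pooled_covariance_identity(self):
        """After centering, pooled covariance equals the weighted mean of
        within-session covariances (exact algebraic identity)."""
        rng = np.random.default_rng(2)
        mats = [rng.normal(rng.normal(0, 3), 1.0, (n, 3))
                for n in (100, 200, 300)]
        out = concatenate_sessions(mats, "center")
        pooled = out.T @ out / out.shape[0]
        within = sum(
            (m - m.mean(0)).T @ (m - m.mean(0)) for m in mats
        ) / out.shape[0]
        np.testing.assert_allclose(pooled, within, rtol=1e-10)

    def test_standardize_mode_unit_sd(self):
        rng = np.random.default_rng(3)
        out = concatenate_sessions([rng.normal(0, 7, (100, 2))], "standardize")
        np.testing.assert_allclose(out.std(axis=0), 1.0, rtol=1e-12)

    def test_node_mismatch_rejected(self, network5_pool, network1_pool):
        with pytest.raises(ValueError, match="mismatch"):
            concatenate_sessions([network5_pool[0], network1_pool[0]])
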