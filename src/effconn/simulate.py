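"""Synthetic resting-state BOLD generator (linear DCM + balloon model).

The generative chain is the one popularized by the Smith et al. network
simulation benchmark:

1. **neuronal dynamics** — dz/dt = sigma * A z + C u, a linear ODE whose
   coupling matrix A has -1 on the diagonal (self-decay) and the causal
   coefficients off it; C is the identity (one exclusive external input per
   region);
2. **external inputs** — u is a two-state (up/down) Poisson switching
   process per region, exponential sojourns with mean 2.5 s up and 10 s
   down, scaled by a fixed amplitude;
3. **hemodynamics** — each region's z drives a balloon model (vasodilatory
   signal, inflow, blood volume, deoxyhemoglobin) whose nonlinear
   observation equation yields the noise-free BOLD signal; per-region
   transit-time jitter gives the hemodynamic response a delay spread of
   about 0.5 s (SD) across regions;
4. **acquisition** — sampling every TR, additive Gaussian measurement noise
   (SD 1), and a Gaussian-weighted running-line high-pass filter with a
   1/200 Hz cutoff (the FSL convention, which preserves the skewness that
   the non-Gaussian search methods rely on).

Integration is explicit Euler at dt = 5 ms for the neuronal stage and for
the balloon stage, whose positive states (flow, volume, deoxyhemoglobin)
are integrated in log space so they cannot cross zero.  Two constants are
calibrated once and frozen (see ``scripts/calibrate_simulator.py``): the
neuronal time constant `SIGMA_DEFAULT`, set so that the mean lag of the
peak cross-correlation between directly connected neuronal signals is
roughly 50 ms, and the BOLD output gain `BOLD_GAIN_DEFAULT`, which fixes
the (arbitrary) signal units so that the average per-node SD of the
noise-free BOLD across the simple-network conditions is near 2 — i.e. an
SNR near 2/1 against the unit-SD measurement noise.  The input amplitude
itself is held at a level that keeps the balloon model in its quasi-linear
regime, where the skewness of the neuronal signals survives into the BOLD
signal (stronger drive saturates the hemodynamic response and washes the
skewness out; sustained strongly negative drive would collapse the
modelled blood flow).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .networks import WeightedConnectivity, check_stability

__all__ = [
    "SimulationConfig",
    "BalloonParams",
    "BoldSession",
    "simulate_inputs",
    "integrate_neuronal",
    "balloon_bold",
    "make_session",
    "concatenate_sessions",
    "highpass_runline",
    "highpass_dct",
]

# Calibrated constants (frozen by scripts/calibrate_simulator.py).
#: neuronal time constant sigma (1/s): mean peak cross-correlation lag
#: between directly connected neuronal signals ~ 50 ms.
SIGMA_DEFAULT = 13.2
#: input amplitude, fixed so neuronal excursions keep the balloon model in
#: its quasi-linear regime: stronger drive saturates the hemodynamic
#: response and erases the BOLD skewness the non-Gaussian methods rely on
#: (and sustained strongly negative drive would collapse the modelled flow).
AMPLITUDE_DEFAULT = 1.0
#: BOLD output gain (the signal is in arbitrary units; this gain makes the
#: mean per-node SD of the noise-free signal across the simple-network
#: conditions land near 2, against measurement noise of unit SD).
BOLD_GAIN_DEFAULT = 5.86
#: SD of per-node transit-time jitter (s) giving an impulse-response
#: peak-latency spread of ~0.5 s across nodes.
TRANSIT_SD_DEFAULT = 0.51


@dataclass
class BalloonParams:
    """Per-node hemodynamic parameters (standard DCM balloon defaults).

    kappa: rate of vasodilatory-signal decay (1/s); gamma: rate of flow
    autoregulation (1/s); tau: mean hemodynamic transit time (s); alpha:
    vessel stiffness exponent; E0: resting oxygen extraction fraction; V0:
    resting venous blood volume fraction.
    """

    kappa: float = 0.65
    gamma: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    E0: float = 0.34
    V0: float = 0.02

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "E0", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"balloon parameter {name} must be positive")


@dataclass
class SimulationConfig:
    """All knobs of one scanning-session simulation."""

    duration: float = 600.0     # session length (s); 600 s at TR 1.2 -> 500 pts
    tr: float = 1.2             # repetition time (s)
    dt: float = 0.005           # integration step (s)
    sigma: float = SIGMA_DEFAULT
    up_mean: float = 2.5        # mean up-state sojourn (s)
    down_mean: float = 10.0     # mean down-state sojourn (s)
    amplitude: float = AMPLITUDE_DEFAULT
    bold_gain: float = BOLD_GAIN_DEFAULT  # output units; see module docstring
    transit_sd: float = TRANSIT_SD_DEFAULT  # hrf delay spread across nodes
    noise_sd: float = 1.0       # measurement noise SD
    highpass_period: float = 200.0  # high-pass cutoff 1/200 Hz, as a period (s)
    highpass: str = "runline"   # "runline" (FSL convention) | "dct" | "none"
    burn_in: float = 12.0       # discarded initial transient (s)
    neuronal_noise_sd: float = 0.0  # optional additive noise on dz/dt, off
    balloon: BalloonParams = field(default_factory=BalloonParams)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0 or self.tr <= 0:
            raise ValueError("dt, duration and tr must be positive")
        if self.dt > self.tr:
            raise ValueError("integration step dt must not exceed TR")
        n = self.duration / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integral number of TRs")

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration / self.tr))


@dataclass
class BoldSession:
    """One simulated scanning session (timepoints x nodes)."""

    nodes: list[str]
    y_clean: np.ndarray     # noise-free BOLD, sampled and filtered
    y_observed: np.ndarray  # y_clean counterpart with measurement noise
    tr: float
    provenance: dict

    @property
    def n_timepoints(self) -> int:
        return self.y_clean.shape[0]


# ---------------------------------------------------------------------------
# Inputs


def simulate_inputs(
    n_nodes: int,
    duration: float,
    dt: float,
    rng: np.random.Generator | int | None = None,
    up_mean: float = 2.5,
    down_mean: float = 10.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Two-state Poisson switching inputs, independent across nodes.

    Each node alternates between an up state (value `amplitude`) and a down
    state (value 0) with exponentially distributed sojourn times of means
    `up_mean` and `down_mean`.  The initial state is drawn from the
    stationary occupancy up_mean / (up_mean + down_mean).
    Returns an array of shape (round(duration/dt), n_nodes).
    """
    if duration <= 0 or dt <= 0 or dt > duration:
        raise ValueError("require 0 < dt <= duration")
    rng = np.random.default_rng(rng)
    n_steps = int(round(duration / dt))
    u = np.zeros((n_steps, n_nodes))
    p_up = up_mean / (up_mean + down_mean)
    for j in range(n_nodes):
        t = 0
        state = rng.random() < p_up
        while t < n_steps:
            sojourn = rng.exponential(up_mean if state else down_mean)
            steps = max(1, int(round(sojourn / dt)))
            if state:
                u[t : t + steps, j] = amplitude
            t += steps
            state = not state
    return u


# ---------------------------------------------------------------------------
# Neuronal dynamics


@njit(cache=True)
def _euler_neuronal(A, sigma, u, dt, noise):  # pragma: no cover - jitted
    n_steps, n = u.shape
    z = np.zeros((n_steps, n))
    for t in range(1, n_steps):
        dz = sigma * (A @ z[t - 1]) + u[t - 1] + noise[t - 1]
        z[t] = z[t - 1] + dt * dz
        s = 0.0
        for j in range(n):
            s += abs(z[t, j])
        if s > 1e9:
            return z[: t + 1]
    return z


def integrate_neuronal(
    net: WeightedConnectivity,
    sigma: float,
    u: np.ndarray,
    dt: float,
    neuronal_noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Explicit-Euler trajectory of dz/dt = sigma*A z + u from z(0) = 0."""
    if not check_stability(net, sigma):
        raise ValueError("network is unstable: dz/dt = sigma*A z would diverge")
    u = np.ascontiguousarray(u, dtype=float)
    if neuronal_noise_sd > 0:
        rng = np.random.default_rng(rng)
        noise = rng.normal(0.0, neuronal_noise_sd, size=u.shape)
    else:
        noise = np.zeros_like(u)
    z = _euler_neuronal(np.ascontiguousarray(net.A), float(sigma), u, float(dt), noise)
    if z.shape[0] < u.shape[0]:
        raise FloatingPointError(
            f"neuronal trajectory diverged at step {z.shape[0]} "
            f"for network over nodes {net.nodes}"
        )
    return z


# ---------------------------------------------------------------------------
# Balloon hemodynamics


@njit(cache=True)
def _euler_balloon(z, dt, kappa, gamma, tau, alpha, E0, V0):  # pragma: no cover
    # flow/volume/deoxyhemoglobin are integrated in log space so the
    # physically positive states cannot cross zero under strong drive
    n_steps, n = z.shape
    y = np.empty((n_steps, n))
    s = np.zeros(n)
    lf = np.zeros(n)  # ln f
    lv = np.zeros(n)  # ln v
    lq = np.zeros(n)  # ln q
    k1 = 7.0 * E0
    k2 = 2.0
    k3 = 2.0 * E0 - 0.2
    ooa = 1.0 / alpha
    for t in range(n_steps):
        for j in range(n):
            f = np.exp(lf[j])
            v = np.exp(lv[j])
            q = np.exp(lq[j])
            y[t, j] = 100.0 * V0 * (
                k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v)
            )
            fout = v ** ooa
            E = 1.0 - (1.0 - E0) ** (1.0 / f)
            ds = z[t, j] - kappa * s[j] - gamma * (f - 1.0)
            dlf = s[j] / f
            dlv = (f - fout) / (tau[j] * v)
            dlq = (f * E / E0 / q - fout / v) / tau[j]
            s[j] += dt * ds
            lf[j] += dt * dlf
            lv[j] += dt * dlv
            lq[j] += dt * dlq
            if (abs(lf[j]) > 20.0 or abs(lv[j]) > 20.0 or abs(lq[j]) > 20.0
                    or abs(s[j]) > 1e6):
                return y[:t]
    return y


def balloon_bold(
    z: np.ndarray,
    params: BalloonParams | None = None,
    dt: float = 0.005,
    transit_times: np.ndarray | None = None,
) -> np.ndarray:
    """Pass neuronal signals through the balloon model; BOLD in percent.

    `transit_times` optionally gives a per-node transit time tau (this is how
    the across-node hemodynamic delay variability is implemented); otherwise
    the shared `params.tau` is used everywhere.
    """
    params = params or BalloonParams()
    z = np.ascontiguousarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("neuronal input to the balloon model must be finite")
    n = z.shape[1]
    if transit_times is None:
        tau = np.full(n, params.tau)
    else:
        tau = np.ascontiguousarray(transit_times, dtype=float)
        if tau.shape != (n,) or np.any(tau <= 0):
            raise ValueError("transit_times must be positive, one per node")
    y = _euler_balloon(
        z, float(dt), params.kappa, params.gamma, tau,
        params.alpha, params.E0, params.V0,
    )
    if y.shape[0] < z.shape[0]:
        raise FloatingPointError(
            f"balloon state became non-physical at step {y.shape[0]}"
        )
    return y


# ---------------------------------------------------------------------------
# High-pass filters


def highpass_runline(Y: np.ndarray, sigma_vols: float) -> np.ndarray:
    """Gaussian-weighted running-line high-pass (FSL bptf convention).

    At each timepoint a weighted linear trend is fitted with Gaussian
    weights of SD `sigma_vols` (in volumes) and subtracted; `sigma_vols` =
    cutoff_period / (2 * TR).
    """
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[0]
    t = np.arange(T)
    offsets = t[None, :] - t[:, None]          # (T, T): column index - row time
    W = np.exp(-0.5 * (offsets / sigma_vols) ** 2)
    M = W * offsets
    S0 = W.sum(axis=1)
    S1 = M.sum(axis=1)
    S2 = (M * offsets).sum(axis=1)
    Sy = W @ Y
    Sxy = M @ Y
    denom = (S0 * S2 - S1 * S1)[:, None]
    trend = (S2[:, None] * Sy - S1[:, None] * Sxy) / denom
    return Y - trend


def highpass_dct(Y: np.ndarray, tr: float, period: float) -> np.ndarray:
    """Simple DCT high-pass: project out cosine regressors slower than `period`."""
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[0]
    n_basis = int(np.floor(2.0 * T * tr / period))
    t = np.arange(T)
    basis = [np.ones(T)]
    for k in range(1, n_basis + 1):
        basis.append(np.cos(np.pi * k * (t + 0.5) / T))
    X = np.column_stack(basis)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


# ---------------------------------------------------------------------------
# Sessions


def _config_hash(config: SimulationConfig, net: WeightedConnectivity) -> str:
    payload = json.dumps(
        {
            "config": {k: v for k, v in vars(config).items() if k != "balloon"},
            "balloon": vars(config.balloon),
            "nodes": net.nodes,
            "A": np.round(net.A, 12).tolist(),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_session(
    config: SimulationConfig,
    net: WeightedConnectivity,
    rng: np.random.Generator | int | None = None,
) -> BoldSession:
    """Simulate one scanning session for the network `net`.

    Pipeline: Poisson inputs -> neuronal Euler integration -> balloon BOLD ->
    sampling every TR (after a discarded burn-in) -> additive measurement
    noise -> high-pass filtering.  Both the noise-free (`y_clean`) and noisy
    (`y_observed`) variants are retained so noise-sensitivity experiments can
    switch measurement noise off.
    """
    rng = np.random.default_rng(rng)
    n = len(net.nodes)
    total = config.burn_in + config.duration

    u = simulate_inputs(
        n, total, config.dt, rng, config.up_mean, config.down_mean, config.amplitude
    )
    z = integrate_neuronal(
        net, config.sigma, u, config.dt, config.neuronal_noise_sd, rng
    )
    transit = config.balloon.tau + rng.normal(0.0, config.transit_sd, size=n)
    transit = np.clip(transit, 0.2, None)  # transit times must stay physical
    y_cont = balloon_bold(z, config.balloon, config.dt, transit)

    step = int(round(config.tr / config.dt))
    start = int(round(config.burn_in / config.dt))
    idx = start + step * np.arange(config.n_timepoints)
    sampled = config.bold_gain * y_cont[idx]

    noisy = sampled + rng.normal(0.0, config.noise_sd, size=sampled.shape)

    if config.highpass == "runline":
        sigma_vols = config.highpass_period / (2.0 * config.tr)
        y_clean = highpass_runline(sampled, sigma_vols)
        y_obs = highpass_runline(noisy, sigma_vols)
    elif config.highpass == "dct":
        y_clean = highpass_dct(sampled, config.tr, config.highpass_period)
        y_obs = highpass_dct(noisy, config.tr, config.highpass_period)
    elif config.highpass == "none":
        y_clean, y_obs = sampled, noisy
    else:
        raise ValueError(f"unknown highpass mode {config.highpass!r}")

    return BoldSession(
        nodes=list(net.nodes),
        y_clean=y_clean,
        y_observed=y_obs,
        tr=config.tr,
        provenance={"config_hash": _config_hash(config, net)},
    )


def concatenate_sessions(
    sessions: list[BoldSession] | list[np.ndarray],
    mode: str = "center",
) -> np.ndarray:
    """Stack sessions after per-session column centering (or standardizing).

    Centering each session before concatenation is essential: differences
    between per-session means otherwise manufacture covariance (and hence
    spurious edges) that none of the individual sessions contain.
    ``mode="standardize"`` additionally scales each column to unit SD, the
    protocol used for empirical multi-subject data.
    """
    mats = []
    nodes = None
    for s in sessions:
        if isinstance(s, BoldSession):
            if nodes is None:
                nodes = s.nodes
            elif s.nodes != nodes:
                raise ValueError("sessions have mismatching node sets")
            m = s.y_observed
        else:
            m = np.asarray(s, dtype=float)
        m = m - m.mean(axis=0)
        if mode == "standardize":
            sd = m.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError("cannot standardize a constant column")
            m = m / sd
        elif mode != "center":
            raise ValueError(f"unknown concatenation mode {mode!r}")
        mats.append(m)
    return np.vstack(mats)


def spectral_exponent(
    z: np.ndarray,
    dt: float = 0.005,
    f_lo: float | None = None,
    f_hi: float | None = None,
    sigma: float = SIGMA_DEFAULT,
    up_mean: float = 2.5,
    down_mean: float = 10.0,
) -> float:
    """Power-law exponent a of p(f) ~ f^-a fitted to the neuronal spectrum.

    A line is fitted to the log-log Welch spectral density, averaged over
    nodes.  By default the fitting band spans the region where the model
    spectrum is power-law-like: from the input-process corner frequency
    (1/up + 1/down) / 2 pi up to the neuronal cutoff sigma / 2 pi (below
    the former the telegraph-input spectrum is flat, well above the latter
    the slope steepens toward the product of the two Lorentzians).
    """
    from scipy import signal as _signal

    if f_lo is None:
        f_lo = (1.0 / up_mean + 1.0 / down_mean) / (2.0 * np.pi)
    if f_hi is None:
        f_hi = sigma / (2.0 * np.pi)
    z = np.asarray(z, dtype=float)
    nperseg = min(2 ** 14, z.shape[0])
    f, p = _signal.welch(z, fs=1.0 / dt, nperseg=nperseg, axis=0)
    band = (f >= f_lo) & (f <= f_hi)
    if band.sum() < 4:
        raise ValueError("too few spectral estimates in the fitting band")
    lf = np.log10(f[band])
    slopes = [
        -np.polyfit(lf, np.log10(p[band][:, j]), 1)[0] for j in range(z.shape[1])
    ]
    return float(np.mean(slopes))


def sessions_noise_off(session: BoldSession) -> BoldSession:
    """A copy of `session` whose observed data is the noise-free variant."""
    return replace(session, y_observed=session.y_clean.copy())
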