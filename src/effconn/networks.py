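"""Ground-truth weighted networks for the simulation studies.

A linear causal system over v nodes is encoded by a square matrix ``A`` with
``A[i, j]`` the coefficient of the edge j -> i and a diagonal of -1 modelling
self-decay of each node.  Off-diagonal coefficients are sampled from a
truncated Gaussian (by rejection, so there are no boundary atoms) and sign
flips turn *amplifying* cycles (coefficient product > 0) into *control*
(inhibitory) cycles.

Nine small cyclic skeletons covering one or more 2-cycles, 4-cycles and a
second-order (cycle-inside-cycle) system are shipped as frozen edge-list
fixtures; :func:`simple_conditions` enumerates the 18 network/variant
simulation conditions built from them.

Cyclic parameterizations can be dynamically unstable, so every sampled
network is screened with :func:`check_stability` (all eigenvalues of sigma*A
in the open left half-plane) and redrawn if needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .graphs import DirectedGraph, graph_from_adjacency, read_graph

__all__ = [
    "WeightedConnectivity",
    "sample_coefficients",
    "check_stability",
    "build_simple_network",
    "simple_network_skeleton",
    "simple_conditions",
    "SIMPLE_VARIANTS",
    "read_weights",
    "write_weights",
]


@dataclass
class WeightedConnectivity:
    """Weight matrix A (A[i, j] = coefficient of edge j -> i, diagonal -1)."""

    nodes: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        v = len(self.nodes)
        if self.A.shape != (v, v):
            raise ValueError("A must be square with one row per node")

    @property
    def skeleton(self) -> DirectedGraph:
        return graph_from_adjacency(self.A, self.nodes)

    def coefficient(self, tail: str, head: str) -> float:
        return self.A[self.nodes.index(head), self.nodes.index(tail)]


def check_stability(net: WeightedConnectivity, sigma: float = 1.0) -> bool:
    """True iff every eigenvalue of sigma*A has strictly negative real part.

    This is asymptotic stability of dz/dt = sigma*A z under bounded input;
    sigma > 0 rescales eigenvalues without moving them across the imaginary
    axis, but is accepted to mirror the simulator's parameterization.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    eigvals = np.linalg.eigvals(sigma * net.A)
    return bool(np.all(eigvals.real < 0))


def sample_coefficients(
    skeleton: DirectedGraph,
    mean: float = 0.5,
    sd: float = 0.1,
    low: float = 0.3,
    high: float = 0.7,
    rng: np.random.Generator | int | None = None,
    signs: dict[tuple[str, str], int] | None = None,
) -> WeightedConnectivity:
    """Sample edge coefficients from a truncated Gaussian.

    Magnitudes are drawn from N(mean, sd) and redrawn (not clipped) until
    they fall in [low, high]; `signs` optionally flips designated edges to
    negative.  The diagonal is set to -1 (self-decay).
    """
    if not low < high:
        raise ValueError("require low < high")
    if sd > 0 and not (low - 8 * sd < mean < high + 8 * sd):
        raise ValueError("truncation window is infeasible for this mean/sd")
    rng = np.random.default_rng(rng)
    nodes = skeleton.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    A = -np.eye(len(nodes))
    for tail, head in sorted(skeleton.edges):
        while True:
            coef = rng.normal(mean, sd) if sd > 0 else mean
            if low <= coef <= high:
                break
        if signs and signs.get((tail, head), 1) < 0:
            coef = -coef
        A[idx[head], idx[tail]] = coef
    return WeightedConnectivity(nodes, A)


# ---------------------------------------------------------------------------
# Simple networks 1-9

#: designated cycles per network (edge lists); control variants flip the sign
#: of the first edge of each selected cycle so its coefficient product < 0.
_DESIGNATED_CYCLES: dict[int, list[list[tuple[str, str]]]] = {
    5: [[("X", "Y"), ("Y", "X")]],
    6: [[("X", "Y"), ("Y", "X")]],
    7: [[("X1", "X2"), ("X2", "X3"), ("X3", "X4"), ("X4", "X1")]],
    8: [
        # outer 6-cycle
        [("X1", "X2"), ("X2", "X3"), ("X3", "X4"), ("X4", "X5"),
         ("X5", "X6"), ("X6", "X1")],
        # inner 4-cycle through the X4 -> X1 chord
        [("X1", "X2"), ("X2", "X3"), ("X3", "X4"), ("X4", "X1")],
    ],
    9: [
        [("A1", "A2"), ("A2", "A3"), ("A3", "A4"), ("A4", "A1")],
        [("A4", "B1"), ("B1", "B2"), ("B2", "B3"), ("B3", "A4")],
    ],
}

#: valid variants per network id; "mixed_ac"/"mixed_ca" set the first/second
#: designated cycle to amplifying and the other to control.
SIMPLE_VARIANTS: dict[int, tuple[str, ...]] = {
    1: ("amplifying",),
    2: ("amplifying",),
    3: ("amplifying",),
    4: ("amplifying",),
    5: ("amplifying", "control"),
    6: ("amplifying", "control"),
    7: ("amplifying", "control"),
    8: ("amplifying", "control", "mixed_ac", "mixed_ca"),
    9: ("amplifying", "control", "mixed_ac", "mixed_ca"),
}


def simple_network_skeleton(network_id: int) -> DirectedGraph:
    """The frozen skeleton fixture for simple network 1..9."""
    if network_id not in range(1, 10):
        raise ValueError(f"unknown simple network id {network_id}")
    ref = resources.files("effconn.data.simple_networks") / f"network{network_id}.edges"
    with resources.as_file(ref) as path:
        return read_graph(path, format="edgelist")


def simple_conditions() -> list[tuple[int, str]]:
    """The 18 simulated (network id, variant) conditions."""
    return [(i, v) for i in range(1, 10) for v in SIMPLE_VARIANTS[i]]


def _variant_signs(network_id: int, variant: str) -> dict[tuple[str, str], int]:
    if variant == "mixed":
        variant = "mixed_ac"
    if variant not in SIMPLE_VARIANTS[network_id] and variant != "mixed_ac":
        raise ValueError(
            f"variant {variant!r} is not defined for network {network_id}"
        )
    cycles = _DESIGNATED_CYCLES.get(network_id, [])
    flags = {
        "amplifying": [False] * len(cycles),
        "control": [True] * len(cycles),
        "mixed_ac": [False, True],
        "mixed_ca": [True, False],
    }[variant]
    signs: dict[tuple[str, str], int] = {}
    for cyc, flip in zip(cycles, flags):
        if flip:
            signs[cyc[0]] = -1
    return signs


def build_simple_network(
    network_id: int,
    variant: str = "amplifying",
    rng_seed: int | np.random.Generator | None = None,
    mean: float = 0.5,
    sd: float = 0.1,
    low: float = 0.3,
    high: float = 0.7,
    max_retries: int = 1000,
) -> WeightedConnectivity:
    """Build a coefficient draw for one of the nine simple networks.

    Coefficients are redrawn until the linear system is stable (unstable
    parameterizations are never released to the simulator).  The test-data
    regime uses mean 0.5, SD 0.1 truncated to [0.3, 0.7]; the training regime
    for parameter tuning uses mean 0.4 truncated to [0.2, 0.6].
    """
    skeleton = simple_network_skeleton(network_id)
    signs = _variant_signs(network_id, variant)
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_retries):
        net = sample_coefficients(skeleton, mean, sd, low, high, rng, signs)
        if check_stability(net):
            return net
    raise RuntimeError(
        f"no stable coefficient draw for network {network_id} ({variant}) "
        f"in {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Weight-matrix I/O

_CONVENTION = "# convention: A[i, j] is the coefficient of edge j -> i (columns are causes)"


def write_weights(net: WeightedConnectivity, path) -> None:
    """Tab-delimited weight matrix with the convention stated in the header."""
    lines = [_CONVENTION, "\t" + "\t".join(net.nodes)]
    for name, row in zip(net.nodes, net.A):
        lines.append(name + "\t" + "\t".join(f"{x:.10g}" for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_weights(path) -> WeightedConnectivity:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    names = lines[0].split("\t")[1:]
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        rows.append([float(c) for c in cells[1:]])
    A = np.array(rows)
    if A.shape != (len(names), len(names)):
        raise ValueError("non-square weight matrix")
    return WeightedConnectivity(names, A)
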