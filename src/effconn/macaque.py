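"""Macaque cortical-connectome blueprints for complex simulations.

Retrograde tracer experiments in the macaque (Markov et al., core-nets.org)
yield a directed axonal network of cortical regions in which each edge
carries a weight (axonal density) and an inter-areal distance in millimetres.
This module loads that table and derives weighted simulation networks from
it:

* ``long_range`` — keep only the edges in the top decile (configurable
  percentile) of the distance distribution, then drop isolated nodes;
* ``degree_prune`` — randomly delete edges until a target average in/out
  degree is reached (used to build sparse subnetworks around a chosen node
  subset);
* ``full`` — the complete network.

Axonal weights are then mapped affinely onto a small coefficient range
(cyclic stability of the dense connectome requires tiny coefficients),
per-dataset heterogeneity is added to a random fraction of coefficients, and
selected 2-cycles can be turned into control cycles by negating one of their
two coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import DirectedGraph
from .networks import WeightedConnectivity

__all__ = ["MacaqueNetwork", "load_macaque_network", "derive_subnetwork"]


@dataclass
class MacaqueNetwork:
    """Directed axonal network with per-edge weight and distance (mm)."""

    edges: pd.DataFrame  # columns: source, target, weight, distance

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["source"]) | set(self.edges["target"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def graph(self) -> DirectedGraph:
        return DirectedGraph(
            self.nodes, zip(self.edges["source"], self.edges["target"])
        )


def load_macaque_network(
    path,
    source_col: str = "source",
    target_col: str = "target",
    weight_col: str = "weight",
    distance_col: str = "distance",
    sep: str | None = None,
) -> MacaqueNetwork:
    """Load a delimited (CSV/TSV) edge table with weights and distances.

    Column names are configurable to accommodate different releases of the
    table.  Duplicate directed edges are rejected; weights and distances must
    be positive numbers.
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    missing = [c for c in (source_col, target_col, weight_col, distance_col)
               if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in macaque table: {missing}")
    df = df.rename(columns={
        source_col: "source", target_col: "target",
        weight_col: "weight", distance_col: "distance",
    })[["source", "target", "weight", "distance"]]
    for col in ("weight", "distance"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] <= 0).any():
            raise ValueError(f"non-positive values in column {col!r}")
    dup = df.duplicated(subset=["source", "target"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["source", "target"]].tolist()
        raise ValueError(f"duplicate directed edge {pair[0]} -> {pair[1]}")
    if (df["source"] == df["target"]).any():
        raise ValueError("self-loops are not allowed in the macaque table")
    return MacaqueNetwork(df.reset_index(drop=True))


def _long_range(net: MacaqueNetwork, percentile: float) -> pd.DataFrame:
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    cutoff = float(np.percentile(net.edges["distance"], percentile))
    return net.edges[net.edges["distance"] >= cutoff].reset_index(drop=True), cutoff


def long_range_cutoff(net: MacaqueNetwork, percentile: float = 90.0) -> float:
    """The distance threshold (mm): linear-interpolation percentile."""
    return _long_range(net, percentile)[1]


def _degree_prune(
    edges: pd.DataFrame, target_degree: float, rng: np.random.Generator
) -> pd.DataFrame:
    nodes = sorted(set(edges["source"]) | set(edges["target"]))
    n_keep = int(round(target_degree * len(nodes)))
    if n_keep > len(edges):
        raise ValueError(
            f"average degree {target_degree} needs {n_keep} edges, "
            f"only {len(edges)} available"
        )
    keep = rng.choice(len(edges), size=n_keep, replace=False)
    return edges.iloc[sorted(keep)].reset_index(drop=True)


def derive_subnetwork(
    net: MacaqueNetwork,
    recipe: str = "full",
    percentile: float = 90.0,
    node_subset: list[str] | None = None,
    target_degree: float = 1.8,
    weight_low: float = 0.05,
    weight_high: float = 0.1,
    heterogeneity_fraction: float = 0.5,
    heterogeneity_mean: float = 0.01,
    heterogeneity_sd: float = 0.01,
    heterogeneity_floor: float | None = None,
    control_2cycles: list[tuple[str, str]] | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> WeightedConnectivity:
    """Derive a weighted simulation network from the axonal table.

    Pipeline: select edges per `recipe` (``long_range`` keeps edges with
    distance at or above the stated percentile and restricts to nodes with at
    least one incident edge; ``degree_prune`` restricts to `node_subset` and
    deletes random edges to hit `target_degree`; ``full`` keeps everything),
    map axonal weights affinely onto [weight_low, weight_high] (min -> low,
    max -> high), perturb a random fraction of coefficients with Gaussian
    heterogeneity (floored at `heterogeneity_floor` when given), and negate
    one coefficient of each pair listed in `control_2cycles`.
    """
    rng = np.random.default_rng(rng_seed)
    if recipe == "long_range":
        edges, _ = _long_range(net, percentile)
    elif recipe == "degree_prune":
        edges = net.edges
        if node_subset is not None:
            edges = edges[
                edges["source"].isin(node_subset) & edges["target"].isin(node_subset)
            ].reset_index(drop=True)
        edges = _degree_prune(edges, target_degree, rng)
    elif recipe == "full":
        edges = net.edges
    else:
        raise ValueError(f"unknown recipe {recipe!r}")

    nodes = sorted(set(edges["source"]) | set(edges["target"]))
    idx = {n: i for i, n in enumerate(nodes)}
    w = edges["weight"].to_numpy(dtype=float)
    wmin, wmax = w.min(), w.max()
    if weight_low == weight_high or wmin == wmax:
        coefs = np.full_like(w, (weight_low + weight_high) / 2.0)
    else:
        coefs = weight_low + (w - wmin) * (weight_high - weight_low) / (wmax - wmin)

    if heterogeneity_fraction > 0:
        n_pert = int(round(heterogeneity_fraction * len(coefs)))
        chosen = rng.choice(len(coefs), size=n_pert, replace=False)
        coefs[chosen] += rng.normal(
            heterogeneity_mean, heterogeneity_sd, size=n_pert
        )
        if heterogeneity_floor is not None:
            coefs = np.maximum(coefs, heterogeneity_floor)

    A = -np.eye(len(nodes))
    for (src, tgt), c in zip(zip(edges["source"], edges["target"]), coefs):
        A[idx[tgt], idx[src]] = c

    if control_2cycles:
        for a, b in control_2cycles:
            if A[idx[b], idx[a]] == 0 or A[idx[a], idx[b]] == 0:
                raise ValueError(f"pair ({a}, {b}) is not a 2-cycle of the subnetwork")
            A[idx[b], idx[a]] = -abs(A[idx[b], idx[a]])

    return WeightedConnectivity(nodes, A)


def synthetic_tracer_table(
    n_nodes: int = 20,
    n_edges: int = 60,
    n_2cycles: int = 6,
    rng_seed: int | np.random.Generator | None = 0,
) -> MacaqueNetwork:
    """SYNTHETIC stand-in for a tracer-derived connectome edge table.

    Generates a random directed network with the requested reciprocity,
    log-normal axonal-density weights and spatially plausible distances
    (nodes scattered in a 60 mm box, distance = Euclidean separation).
    This is *not* empirical data; it exists so the loading and subnetwork
    recipes can be exercised without the published table.
    """
    rng = np.random.default_rng(rng_seed)
    nodes = [f"R{i+1:02d}" for i in range(n_nodes)]
    pos = rng.uniform(0, 60, size=(n_nodes, 3))
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i < j]
    rng.shuffle(pairs)
    edges = []
    need_mutual = n_2cycles
    for i, j in pairs:
        if len(edges) >= n_edges:
            break
        if need_mutual > 0 and len(edges) + 2 <= n_edges:
            edges += [(i, j), (j, i)]
            need_mutual -= 1
        else:
            edges.append((i, j) if rng.random() < 0.5 else (j, i))
    rows = [
        {
            "source": nodes[i],
            "target": nodes[j],
            "weight": float(rng.lognormal(-2.0, 1.0)),
            "distance": float(np.linalg.norm(pos[i] - pos[j])),
        }
        for i, j in edges
    ]
    return MacaqueNetwork(pd.DataFrame(rows))


def synthetic_long_range_network(
    rng_seed: int | np.random.Generator | None = 0,
    n_nodes: int = 67,
    n_edges: int = 161,
    n_2cycles: int = 19,
    weight_low: float = 0.05,
    weight_high: float = 0.1,
) -> WeightedConnectivity:
    """SYNTHETIC stand-in for the long-range cortical subnetwork.

    A random sparse directed graph with the long-range case's summary
    statistics (67 nodes, 161 directed edges of which 19 reciprocal pairs,
    average in/out degree 2.4) and base coefficients in the stated small
    range [0.05, 0.1].  Apart from the reciprocal pairs, edges follow a
    random node ordering (a random DAG), so the cycle census stays in the
    low hundreds as in the spatially constrained cortical subnetwork — a
    plain random digraph at this density would contain millions of simple
    cycles.  Per-dataset heterogeneity is applied separately (see
    :func:`heterogeneous_draw`).  This is *not* the empirical network; it
    reproduces the regime (density, reciprocity, tiny coefficients), not
    the wiring.
    """
    rng = np.random.default_rng(rng_seed)
    nodes = [f"R{i+1:02d}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    rank = np.empty(n_nodes, dtype=int)
    rank[order] = np.arange(n_nodes)
    edges: set[tuple[int, int]] = set()
    mutual = 0
    while mutual < n_2cycles:
        i, j = rng.integers(0, n_nodes, 2)
        if i != j and (i, j) not in edges and (j, i) not in edges:
            edges.add((int(i), int(j)))
            edges.add((int(j), int(i)))
            mutual += 1
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_nodes, 2)
        if i == j or (i, j) in edges or (j, i) in edges:
            continue
        if rank[i] > rank[j]:
            i, j = j, i
        edges.add((int(i), int(j)))
    A = -np.eye(n_nodes)
    for i, j in edges:
        A[j, i] = rng.uniform(weight_low, weight_high)
    return WeightedConnectivity(nodes, A)


def heterogeneous_draw(
    base: WeightedConnectivity,
    rng: np.random.Generator | int | None = None,
    fraction: float = 0.5,
    mean: float = 0.01,
    sd: float = 0.01,
    floor: float | None = None,
) -> WeightedConnectivity:
    """Per-dataset heterogeneity: perturb a random fraction of coefficients.

    Gaussian values are added to the chosen coefficients; magnitudes are
    floored when `floor` is given.  The sign of each coefficient is
    preserved (control cycles stay control cycles).
    """
    rng = np.random.default_rng(rng)
    A = base.A.copy()
    rows, cols = np.nonzero(A - np.diag(np.diag(A)))
    n_pert = int(round(fraction * len(rows)))
    chosen = rng.choice(len(rows), size=n_pert, replace=False)
    for k in chosen:
        i, j = rows[k], cols[k]
        sign = np.sign(A[i, j])
        mag = abs(A[i, j]) + rng.normal(mean, sd)
        if floor is not None:
            mag = max(mag, floor)
        A[i, j] = sign * max(mag, 1e-6)
    return WeightedConnectivity(base.nodes, A)
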