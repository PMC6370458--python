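"""Directed-graph data model and text I/O.

The central object is :class:`DirectedGraph`: a node-labelled set of directed
edges in which 2-cycles (X -> Y together with Y -> X, i.e. direct feedback)
are allowed and self-loops are not.  Self-decay lives on the diagonal of the
simulator's weight matrices, never in the graph.

Two plain-text formats are supported:

* edge lists: one ``tail -> head`` per line, ``#`` comments, plus an optional
  ``# nodes: A B C`` header so that isolated nodes survive a round-trip;
* adjacency matrices: tab-delimited with a header row and column of node
  names, where a nonzero entry means tail(row) -> head(column).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["DirectedGraph", "GraphParseError", "read_graph", "write_graph"]


class GraphParseError(ValueError):
    """Raised for malformed graph files; the message names the offending line."""


class DirectedGraph:
    """A directed graph over named nodes; 2-cycles allowed, self-loops not.

    Parameters
    ----------
    nodes : iterable of str
        Ordered node labels.  Order matters only for display and matrix I/O.
    edges : iterable of (str, str), optional
        Directed edges as (tail, head) pairs.  Both endpoints must appear in
        `nodes`; self-loops raise ``ValueError``.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        self._nodeset = set(self.nodes)
        self.edges: set[tuple[str, str]] = set()
        for tail, head in edges:
            self.add_edge(tail, head)

    def add_edge(self, tail: str, head: str) -> None:
        if tail == head:
            raise ValueError(f"self-loop {tail!r} -> {head!r} not allowed")
        if tail not in self._nodeset or head not in self._nodeset:
            missing = tail if tail not in self._nodeset else head
            raise ValueError(f"edge endpoint {missing!r} is not a declared node")
        self.edges.add((tail, head))

    def has_edge(self, tail: str, head: str) -> bool:
        return (tail, head) in self.edges

    # -- derived edge sets -------------------------------------------------

    def adjacencies(self) -> set[frozenset[str]]:
        """Unordered connected pairs; a 2-cycle counts as one adjacency."""
        return {frozenset(e) for e in self.edges}

    def two_cycles(self) -> set[frozenset[str]]:
        """Unordered pairs with both directions present."""
        return {
            frozenset((a, b)) for a, b in self.edges if (b, a) in self.edges
        }

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self._nodeset == other._nodeset and self.edges == other.edges

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.edges))

    def __repr__(self) -> str:
        return (
            f"DirectedGraph({len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"{len(self.two_cycles())} 2-cycles)"
        )


# ---------------------------------------------------------------------------
# I/O


def _parse_edgelist(text: str) -> DirectedGraph:
    declared: list[str] | None = None
    edges: list[tuple[str, str]] = []
    seen_nodes: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.lower().startswith("# nodes:"):
            declared = line.split(":", 1)[1].split()
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3 or parts[1] not in ("->", "--"):
            raise GraphParseError(f"line {lineno}: malformed edge line {raw!r}")
        tail, op, head = parts
        for tok in (tail, head):
            if declared is not None and tok not in declared:
                raise GraphParseError(f"line {lineno}: unknown node token {tok!r}")
            if tok not in seen_nodes:
                seen_nodes.append(tok)
        edges.append((tail, head))
        if op == "--":  # undirected dialect: emit both directions
            edges.append((head, tail))
    nodes = declared if declared is not None else seen_nodes
    try:
        return DirectedGraph(nodes, edges)
    except ValueError as exc:
        raise GraphParseError(str(exc)) from exc


def _parse_matrix(text: str) -> DirectedGraph:
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise GraphParseError("empty matrix file")
    header = lines[0].split("\t")
    names = header[1:] if header[0] == "" else header
    rows = lines[1:]
    if len(rows) != len(names):
        raise GraphParseError(
            f"non-square matrix: {len(names)} columns but {len(rows)} rows"
        )
    g = DirectedGraph(names)
    for lineno, row in enumerate(rows, start=2):
        cells = row.split("\t")
        tail = cells[0]
        if tail not in g._nodeset:
            raise GraphParseError(f"line {lineno}: unknown node token {tail!r}")
        if len(cells) - 1 != len(names):
            raise GraphParseError(f"line {lineno}: ragged row")
        for head, cell in zip(names, cells[1:]):
            try:
                val = float(cell)
            except ValueError as exc:
                raise GraphParseError(
                    f"line {lineno}: non-numeric entry {cell!r}"
                ) from exc
            if val != 0.0 and tail != head:
                g.add_edge(tail, head)
    return g


def read_graph(path, format: str = "edgelist") -> DirectedGraph:
    """Read a :class:`DirectedGraph` from `path`.

    ``format="edgelist"`` expects ``tail -> head`` lines; ``format="matrix"``
    expects a tab-delimited square matrix with node names on the header row
    and first column (rows are tails).
    """
    with open(path) as fh:
        text = fh.read()
    if format == "edgelist":
        return _parse_edgelist(text)
    if format == "matrix":
        return _parse_matrix(text)
    raise ValueError(f"unknown graph format {format!r}")


def write_graph(graph: DirectedGraph, path, format: str = "edgelist") -> None:
    """Write `graph` to `path` in the chosen text format (rows are tails)."""
    if format == "edgelist":
        lines = ["# nodes: " + " ".join(graph.nodes)]
        lines += [f"{t} -> {h}" for t, h in sorted(graph.edges)]
        text = "\n".join(lines) + "\n"
    elif format == "matrix":
        mat = pd.DataFrame(
            0, index=graph.nodes, columns=graph.nodes, dtype=int
        )
        for tail, head in graph.edges:
            mat.loc[tail, head] = 1
        text = (
            "# adjacency matrix: rows are tails (causes), columns are heads\n"
            + mat.to_csv(sep="\t")
        )
    else:
        raise ValueError(f"unknown graph format {format!r}")
    with open(path, "w") as fh:
        fh.write(text)


def graph_from_adjacency(A: np.ndarray, nodes: list[str]) -> DirectedGraph:
    """Graph skeleton of a weight matrix with the A[i, j] = j -> i convention."""
    g = DirectedGraph(nodes)
    v = len(nodes)
    for i in range(v):
        for j in range(v):
            if i != j and A[i, j] != 0.0:
                g.add_edge(nodes[j], nodes[i])
    return g
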