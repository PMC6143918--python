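"""Weighted graph data model and edge-list I/O.

The graph classes here are deliberately minimal: undirected weighted graphs
with optional self-loops (which appear only through community aggregation),
and a directed counterpart used solely as input to preprocessing.

Conventions
-----------
* Node identifiers are opaque, hashable, orderable values; file I/O always
  produces strings.  Wherever a deterministic order is needed, nodes are
  sorted.
* A self-loop on ``v`` with weight ``w`` contributes ``2 * w`` to the
  strength of ``v`` and ``w`` to the total weight ``m``, so that
  ``sum(strength) == 2 * m`` holds exactly.  This matches the standard
  modularity bookkeeping.
* Edge weights are non-negative reals.
"""

from __future__ import annotations

import os
from typing import Dict, Hashable, Iterable, Iterator, Set, Tuple

from .errors import EdgeListParseError, ValidationError

Node = Hashable


class WeightedGraph:
    """Undirected weighted graph with self-loops.

    Internally an adjacency map ``node -> {neighbor -> weight}`` kept
    symmetric, plus a separate ``node -> weight`` map for self-loops.
    """

    __slots__ = ("_adj", "_loops")

    def __init__(self) -> None:
        self._adj: Dict[Node, Dict[Node, float]] = {}
        self._loops: Dict[Node, float] = {}

    # -- construction -------------------------------------------------

    def add_node(self, v: Node) -> None:
        self._adj.setdefault(v, {})

    def add_edge(self, u: Node, v: Node, weight: float) -> None:
        """Add an edge (or a self-loop when ``u == v``).

        Raises
        ------
        ValidationError
            If the weight is negative or the unordered pair already exists.
        """
        if weight < 0:
            raise ValidationError(f"negative edge weight {weight!r} on ({u!r}, {v!r})")
        self.add_node(u)
        self.add_node(v)
        if u == v:
            if u in self._loops:
                raise ValidationError(f"duplicate self-loop on node {u!r}")
            self._loops[u] = float(weight)
            return
        if v in self._adj[u]:
            raise ValidationError(f"duplicate edge ({u!r}, {v!r})")
        self._adj[u][v] = float(weight)
        self._adj[v][u] = float(weight)

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> Set[Node]:
        return set(self._adj)

    def __contains__(self, v: Node) -> bool:
        return v in self._adj

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def number_of_edges(self) -> int:
        """Count of distinct unordered pairs, self-loops included."""
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2 + len(self._loops)

    def neighbors(self, v: Node) -> Dict[Node, float]:
        """Mapping neighbor -> weight (self excluded even with a loop)."""
        try:
            return self._adj[v]
        except KeyError:
            raise KeyError(f"node {v!r} not in graph") from None

    def self_loop(self, v: Node) -> float:
        if v not in self._adj:
            raise KeyError(f"node {v!r} not in graph")
        return self._loops.get(v, 0.0)

    @property
    def self_loops(self) -> Dict[Node, float]:
        return dict(self._loops)

    def edge_weight(self, u: Node, v: Node) -> float:
        """Weight of edge {u, v}, 0.0 if absent. Self-loop weight if u == v."""
        if u == v:
            return self.self_loop(u)
        return self.neighbors(u).get(v, 0.0)

    def edges(self) -> Iterator[Tuple[Node, Node, float]]:
        """Yield (u, v, w) with u < v, sorted; then self-loops (v, v, w) sorted."""
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if u < v:
                    yield u, v, self._adj[u][v]
        for v in sorted(self._loops):
            yield v, v, self._loops[v]

    def strength(self, v: Node) -> float:
        """s_v = sum of incident edge weights, self-loops counted twice."""
        return sum(self.neighbors(v).values()) + 2.0 * self._loops.get(v, 0.0)

    def total_weight(self) -> float:
        """m = sum of edge weights plus self-loop weights."""
        half = sum(w for nbrs in self._adj.values() for w in nbrs.values()) / 2.0
        return half + sum(self._loops.values())

    def subgraph(self, members: Iterable[Node]) -> "WeightedGraph":
        """Induced subgraph on ``members``; weights are kept unchanged."""
        members = set(members)
        missing = members - set(self._adj)
        if missing:
            raise KeyError(f"nodes not in graph: {sorted(map(repr, missing))}")
        sub = WeightedGraph()
        for v in members:
            sub.add_node(v)
            if v in self._loops:
                sub._loops[v] = self._loops[v]
            for u, w in self._adj[v].items():
                if u in members:
                    sub._adj[v][u] = w
        return sub

    def copy(self) -> "WeightedGraph":
        return self.subgraph(self._adj)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedGraph):
            return NotImplemented
        return self._adj == other._adj and self._loops == other._loops

    def __repr__(self) -> str:
        return (
            f"<WeightedGraph n={self.number_of_nodes()} "
            f"edges={self.number_of_edges()} m={self.total_weight():.6g}>"
        )


class DirectedWeightedGraph:
    """Directed weighted graph: arcs (u, v) and (v, u) are independent."""

    __slots__ = ("_succ",)

    def __init__(self) -> None:
        self._succ: Dict[Node, Dict[Node, float]] = {}

    def add_node(self, v: Node) -> None:
        self._succ.setdefault(v, {})

    def add_arc(self, u: Node, v: Node, weight: float) -> None:
        if weight < 0:
            raise ValidationError(f"negative arc weight {weight!r} on ({u!r}, {v!r})")
        self.add_node(u)
        self.add_node(v)
        if v in self._succ[u]:
            raise ValidationError(f"duplicate arc ({u!r}, {v!r})")
        self._succ[u][v] = float(weight)

    @property
    def nodes(self) -> Set[Node]:
        return set(self._succ)

    def arc_weight(self, u: Node, v: Node) -> float:
        return self._succ.get(u, {}).get(v, 0.0)

    def arcs(self) -> Iterator[Tuple[Node, Node, float]]:
        for u in sorted(self._succ):
            for v in sorted(self._succ[u]):
                yield u, v, self._succ[u][v]

    def number_of_arcs(self) -> int:
        return sum(len(s) for s in self._succ.values())

    def __repr__(self) -> str:
        return f"<DirectedWeightedGraph n={len(self._succ)} arcs={self.number_of_arcs()}>"


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def node_strength(g: WeightedGraph, v: Node) -> float:
    """Strength of ``v``: incident edge weights, self-loops counted twice."""
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return g.strength(v)


def induced_subgraph(g: WeightedGraph, members: Iterable[Node]) -> WeightedGraph:
    """Subgraph induced by ``members``; original weights preserved."""
    return g.subgraph(members)


def read_edge_list(path: os.PathLike | str, directed: bool = False):
    """Parse a tab/whitespace-separated edge list.

    Each non-blank, non-comment line is ``node_a  node_b  [weight]`` with a
    default weight of 1.0.  Lines with identical endpoints become
    self-loops.  For undirected input a repeated unordered pair is an error;
    for directed input each ordered pair may appear once.

    Returns a :class:`WeightedGraph` or, with ``directed=True``, a
    :class:`DirectedWeightedGraph`.
    """
    g = DirectedWeightedGraph() if directed else WeightedGraph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise EdgeListParseError(lineno, f"expected >= 2 fields, got {len(fields)}")
            if len(fields) > 3:
                raise EdgeListParseError(lineno, f"expected <= 3 fields, got {len(fields)}")
            u, v = fields[0], fields[1]
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise EdgeListParseError(lineno, f"unparsable weight {fields[2]!r}") from None
                if w != w:  # NaN
                    raise EdgeListParseError(lineno, "weight is NaN")
                if w < 0:
                    raise EdgeListParseError(lineno, f"negative weight {w!r}")
            else:
                w = 1.0
            try:
                if directed:
                    g.add_arc(u, v, w)
                else:
                    g.add_edge(u, v, w)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
    return g


def write_edge_list(g: WeightedGraph, path: os.PathLike | str) -> None:
    """Write a tab-separated edge list, edges sorted by (node_a, node_b).

    Weights are printed with 6 significant digits; a read/write round-trip
    reproduces the graph for weights representable at that precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in g.edges():
            fh.write(f"{u}\t{v}\t{w:.6g}\n")
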