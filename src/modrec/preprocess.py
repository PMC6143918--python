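"""Network standardization: directed-to-undirected conversion and weight
normalization into [0, 1].

Both steps preserve the node set.  ``to_undirected`` averages the two arc
weights of each unordered pair, treating a missing reverse arc as weight 0;
pairs whose average is exactly 0 carry no information for weighted
clustering and are dropped.  ``normalize_weights`` divides every weight by
the global maximum, so the result has maximum weight exactly 1.0 and is
idempotent.
"""

from __future__ import annotations

from .errors import ValidationError
from .graph import DirectedWeightedGraph, WeightedGraph


def to_undirected(g: DirectedWeightedGraph) -> WeightedGraph:
    """Collapse arcs to undirected edges by averaging the two directions.

    For every unordered pair {u, v} with at least one arc, the undirected
    weight is ``(w(u, v) + w(v, u)) / 2`` with missing arcs contributing 0.
    Self-arcs become self-loops with their weight unchanged (the "average"
    of a single direction with itself).  Zero-average pairs are dropped.
    """
    und = WeightedGraph()
    for v in g.nodes:
        und.add_node(v)
    seen: set = set()
    for u, v, w in g.arcs():
        if u == v:
            und.add_edge(u, u, w)
            continue
        pair = (u, v) if u < v else (v, u)
        if pair in seen:
            continue
        seen.add(pair)
        avg = (g.arc_weight(u, v) + g.arc_weight(v, u)) / 2.0
        if avg > 0.0:
            und.add_edge(pair[0], pair[1], avg)
    return und


def normalize_weights(g: WeightedGraph) -> WeightedGraph:
    """Divide all edge and self-loop weights by the maximum weight.

    Raises
    ------
    ValidationError
        If the graph has no edges or every weight is zero (the maximum is
        not a valid divisor).
    """
    weights = [w for _, _, w in g.edges()]
    if not weights:
        raise ValidationError("cannot normalize a graph with no edges")
    wmax = max(weights)
    if wmax <= 0.0:
        raise ValidationError("cannot normalize a graph whose weights are all zero")
    out = WeightedGraph()
    for v in g.nodes:
        out.add_node(v)
    for u, v, w in g.edges():
        out.add_edge(u, v, w / wmax)
    return out
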