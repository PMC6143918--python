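"""Independent oracles: deliberately naive, brute-force re-derivations used
to check the package's fast paths. Nothing here may import the algorithmic
internals under test (only the graph container, for reading structure)."""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Iterator, List, Sequence, Set, Tuple

import numpy as np

from modrec.graph import WeightedGraph


def all_set_partitions(items: Sequence) -> Iterator[List[Set]]:
    """Enumerate every partition of ``items`` (Bell(n) of them)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in all_set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1 :]
        yield partial + [{first}]


def modularity_direct(g: WeightedGraph, blocks: Iterable[Iterable]) -> float:
    """Evaluate Q = (1/2m) sum_ij [A_ij - s_i s_j / 2m] delta(c_i, c_j)
    term by term over all ordered node pairs, with A_ii = 2 * self-loop."""
    nodes = sorted(g.nodes, key=str)
    label = {}
    for c, block in enumerate(blocks):
        for v in block:
            label[v] = c
    m = g.total_weight()
    two_m = 2.0 * m
    q = 0.0
    for i in nodes:
        for j in nodes:
            if label[i] != label[j]:
                continue
            a_ij = 2.0 * g.self_loop(i) if i == j else g.neighbors(i).get(j, 0.0)
            q += a_ij - g.strength(i) * g.strength(j) / two_m
    return q / two_m


def max_modularity_exhaustive(g: WeightedGraph) -> Tuple[float, List[Set]]:
    """Best modularity over every partition of the node set (n <= 10)."""
    nodes = sorted(g.nodes, key=str)
    assert len(nodes) <= 10, "exhaustive oracle limited to 10 nodes"
    best_q, best_blocks = -np.inf, None
    for blocks in all_set_partitions(nodes):
        q = modularity_direct(g, blocks)
        if q > best_q:
            best_q, best_blocks = q, [set(b) for b in blocks]
    return best_q, best_blocks


def dense_pagerank(g: WeightedGraph, damping: float = 0.85, iters: int = 10_000) -> dict:
    """Power iteration on the explicitly built dense Google matrix."""
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for v in nodes:
        for u, w in g.neighbors(v).items():
            A[idx[v], idx[u]] = w
        A[idx[v], idx[v]] = 2.0 * g.self_loop(v)
    s = A.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        if s[i] > 0:
            P[i] = A[i] / s[i]
        else:
            P[i] = 1.0 / n  # dangling: uniform teleport
    G = (1.0 - damping) / n * np.ones((n, n)) + damping * P
    x = np.full(n, 1.0 / n)
    for _ in range(iters):
        x_new = x @ G
        if np.abs(x_new - x).sum() < 1e-14:
            x = x_new
            break
        x = x_new
    return {v: float(x[idx[v]]) for v in nodes}


def nmi_contingency(blocks_p: List[Set], blocks_q: List[Set]) -> float:
    """NMI from the contingency table, normalized by mean entropy."""
    n = sum(len(b) for b in blocks_p)
    h_p = -sum(len(b) / n * np.log(len(b) / n) for b in blocks_p)
    h_q = -sum(len(b) / n * np.log(len(b) / n) for b in blocks_q)
    if h_p == 0.0 and h_q == 0.0:
        return 1.0
    mi = 0.0
    for bp in blocks_p:
        for bq in blocks_q:
            c = len(bp & bq)
            if c > 0:
                mi += c / n * np.log(n * c / (len(bp) * len(bq)))
    return 2.0 * mi / (h_p + h_q)


def make_clique(names: Sequence[str], weight: float = 1.0) -> WeightedGraph:
    g = WeightedGraph()
    for v in names:
        g.add_node(v)
    for u, v in combinations(names, 2):
        g.add_edge(u, v, weight)
    return g
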