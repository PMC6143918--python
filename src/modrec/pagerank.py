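"""Edge-weight-aware PageRank and the seed partition built from it.

The random surfer moves from ``u`` to neighbor ``v`` with probability
``w(u, v) / s_u`` (self-loops contribute ``2 * loop / s`` to staying put),
and teleports uniformly with probability ``1 - damping``.  Zero-strength
nodes redistribute their mass uniformly over all nodes, the standard
stochastic completion for dangling states.

The seed partition attaches each node to its highest-scoring neighbor —
or keeps it alone when no neighbor scores strictly higher — and takes
connected components of the resulting pointer graph as communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy import sparse

from .errors import ValidationError
from .graph import Node, WeightedGraph
from .louvain import Partition


@dataclass(frozen=True)
class PageRankVector:
    """Per-node authority scores summing to 1."""

    scores: Dict[Node, float]
    damping: float
    iterations_used: int
    converged: bool = True

    def __getitem__(self, v: Node) -> float:
        return self.scores[v]

    def covers(self, g: WeightedGraph) -> bool:
        return g.nodes <= set(self.scores)


def weighted_pagerank(
    g: WeightedGraph,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> PageRankVector:
    """Power-iterate the weighted PageRank fixed point.

        PR(v) = (1 - d)/N + d * sum_u PR(u) * w(u, v) / s_u

    starting from the uniform vector, stopping when the L1 change drops
    below ``tol``.  Non-convergence within ``max_iter`` emits a warning and
    returns the last iterate with ``converged=False``.
    """
    if not (0.0 < damping < 1.0):
        raise ValidationError(f"damping must be in (0, 1), got {damping}")
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValidationError("pagerank undefined for an empty graph")
    index = {v: i for i, v in enumerate(nodes)}

    strengths = np.array([g.strength(v) for v in nodes], dtype=float)
    dangling = strengths <= 0.0

    rows, cols, vals = [], [], []
    for v in nodes:
        j = index[v]
        for u, w in g.neighbors(v).items():
            if w > 0.0:
                rows.append(index[u])
                cols.append(j)
                vals.append(w)
        loop = g.self_loop(v)
        if loop > 0.0:
            rows.append(j)
            cols.append(j)
            vals.append(2.0 * loop)  # A_vv = 2 * self-loop weight
    # transition matrix P[u, v] = A_uv / s_u; x @ P propagates mass u -> v
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_s = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, strengths))
    P = sparse.csr_array(
        (np.asarray(vals) * inv_s[rows], (rows, cols)), shape=(n, n)
    )

    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dangling_mass = float(x[dangling].sum())
        x_new = teleport + damping * (x @ P + dangling_mass / n)
        delta = float(np.abs(x_new - x).sum())
        x = x_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"pagerank did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return PageRankVector(
        scores={v: float(x[index[v]]) for v in nodes},
        damping=damping,
        iterations_used=iterations,
        converged=converged,
    )


def seed_partition(g: WeightedGraph, pr: PageRankVector) -> Partition:
    """Initial Louvain partition: each node joins its top-PageRank neighbor.

    Each node is labeled with the id of the neighbor holding the highest
    score — if that score is strictly greater than its own — or with its own
    id otherwise.  Ties among equally scored neighbors go to the smallest
    node id.  Blocks are the preimages of this representative map, which
    keeps the seed fine-grained (one block per chosen representative) rather
    than collapsing whole basins of attraction into single communities: a
    one-block seed would be a fixed point of the local-move phase and defeat
    the recursive splitting downstream.  Isolated nodes form singletons.
    """
    if not pr.covers(g):
        raise ValidationError("pagerank vector does not cover all graph nodes")
    labels: Dict[Node, Node] = {}
    for v in g.nodes:
        best = None
        best_score = -np.inf
        for u in sorted(g.neighbors(v), key=str):
            score = pr[u]
            if score > best_score:
                best, best_score = u, score
        labels[v] = best if (best is not None and best_score > pr[v]) else v
    return Partition(labels)
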