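"""Louvain modularity optimization accepting an arbitrary initial partition.

The quality function is the weighted Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - s_i * s_j / (2m)] * delta(c_i, c_j)

with ``A_ii`` equal to twice the self-loop weight, so that node strengths
sum to ``2m``.  The optimizer is the classic two-phase scheme: greedy local
node moves until no strictly positive modularity gain remains, then
aggregation of communities into supernodes, iterated until the modularity
stops increasing.  Unlike the stock algorithm, the level-0 starting point
is whatever partition the caller supplies (here: the PageRank seed).

Node visit order within each sweep is shuffled by a seeded RNG, which makes
runs stochastic but reproducible; ties between equally good destination
communities are broken toward the smallest community label.
"""

from __future__ import annotations

import random
from collections import defaultdict
from typing import Callable, Dict, Hashable, Iterable, Mapping, Optional, Set, Tuple

from .errors import ValidationError
from .graph import Node, WeightedGraph

Label = Hashable

#: moves must improve Q by more than this to be accepted (float-livelock guard)
MIN_GAIN = 1e-12

MoveCallback = Callable[[WeightedGraph, Dict[Node, int], float], None]


class Partition:
    """Assignment of every node to exactly one community label.

    Labels are opaque; blocks (label -> set of nodes) are derived on demand.
    """

    __slots__ = ("_assignment",)

    def __init__(self, assignment: Mapping[Node, Label]):
        self._assignment = dict(assignment)

    @classmethod
    def singletons(cls, nodes: Iterable[Node]) -> "Partition":
        return cls({v: v for v in nodes})

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[Node]]) -> "Partition":
        assignment: Dict[Node, int] = {}
        for label, block in enumerate(blocks):
            for v in block:
                if v in assignment:
                    raise ValidationError(f"node {v!r} appears in two blocks")
                assignment[v] = label
        return cls(assignment)

    @property
    def assignment(self) -> Dict[Node, Label]:
        return dict(self._assignment)

    def label_of(self, v: Node) -> Label:
        return self._assignment[v]

    @property
    def nodes(self) -> Set[Node]:
        return set(self._assignment)

    def blocks(self) -> Dict[Label, Set[Node]]:
        out: Dict[Label, Set[Node]] = defaultdict(set)
        for v, c in self._assignment.items():
            out[c].add(v)
        return dict(out)

    def block_list(self) -> list[frozenset]:
        """Blocks as frozensets, sorted by their smallest member (determinism)."""
        return sorted(
            (frozenset(b) for b in self.blocks().values()),
            key=lambda b: min(map(str, b)),
        )

    def number_of_blocks(self) -> int:
        return len(set(self._assignment.values()))

    def __len__(self) -> int:
        return len(self._assignment)

    def __eq__(self, other: object) -> bool:
        """Equality up to relabeling of communities."""
        if not isinstance(other, Partition):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        return self.block_list() == other.block_list()

    def __repr__(self) -> str:
        return f"<Partition n={len(self)} blocks={self.number_of_blocks()}>"

    def validate_for(self, g: WeightedGraph) -> None:
        if self.nodes != g.nodes:
            raise ValidationError("partition does not cover exactly the graph's nodes")


def _canonical_labels(g: WeightedGraph, p: Partition) -> Dict[Node, int]:
    """Relabel communities as 0..K-1, ordered by smallest member node id."""
    blocks = sorted(p.blocks().values(), key=lambda b: min(map(str, b)))
    labels: Dict[Node, int] = {}
    for i, block in enumerate(blocks):
        for v in block:
            labels[v] = i
    return labels


def modularity(g: WeightedGraph, p: Partition) -> float:
    """Newman-Girvan modularity of ``p`` on ``g``; requires m > 0."""
    p.validate_for(g)
    m = g.total_weight()
    if m <= 0.0:
        raise ValidationError("modularity undefined for a graph with zero total weight")
    two_m = 2.0 * m
    sigma_in: Dict[Label, float] = defaultdict(float)   # sum_{i,j in C} A_ij
    sigma_tot: Dict[Label, float] = defaultdict(float)  # sum of member strengths
    assignment = p._assignment
    for v in g.nodes:
        sigma_tot[assignment[v]] += g.strength(v)
    for u, v, w in g.edges():
        if u == v:
            sigma_in[assignment[u]] += 2.0 * w
        elif assignment[u] == assignment[v]:
            sigma_in[assignment[u]] += 2.0 * w
    return sum(
        sigma_in[c] / two_m - (sigma_tot[c] / two_m) ** 2 for c in sigma_tot
    )


def local_move_phase(
    g: WeightedGraph,
    p: Partition,
    rng_seed: Optional[int] = None,
    *,
    rng: Optional[random.Random] = None,
    shuffle: bool = True,
    on_move: Optional[MoveCallback] = None,
) -> Partition:
    """Greedy node-by-node moves until a full sweep yields no improvement.

    Each node is tentatively removed from its community and placed in the
    neighboring community (or back in its own) with the largest strictly
    positive modularity gain.  The visit order is reshuffled every sweep
    when ``shuffle`` is true; with ``shuffle=False`` nodes are visited in
    sorted order, which is handy for deterministic tests.

    ``on_move(graph, labels, q)`` is invoked after every accepted move with
    a snapshot of the assignment and the incrementally tracked modularity.
    """
    p.validate_for(g)
    m = g.total_weight()
    if m <= 0.0:
        raise ValidationError("local moves undefined for a graph with zero total weight")
    if rng is None:
        rng = random.Random(rng_seed)

    labels = _canonical_labels(g, p)
    strengths = {v: g.strength(v) for v in g.nodes}
    loops = {v: g.self_loop(v) for v in g.nodes}
    two_m = 2.0 * m

    sigma_tot: Dict[int, float] = defaultdict(float)
    sigma_in: Dict[int, float] = defaultdict(float)
    for v, s in strengths.items():
        sigma_tot[labels[v]] += s
        sigma_in[labels[v]] += 2.0 * loops[v]
    for u in g.nodes:
        cu = labels[u]
        for v, w in g.neighbors(u).items():
            if labels[v] == cu:
                sigma_in[cu] += w  # each intra edge hit twice -> contributes 2w

    q = sum(sigma_in[c] / two_m - (sigma_tot[c] / two_m) ** 2 for c in sigma_tot)

    order = sorted(g.nodes, key=str)
    improved = True
    while improved:
        improved = False
        if shuffle:
            rng.shuffle(order)
        for v in order:
            c_old = labels[v]
            s_v = strengths[v]
            loop_v = loops[v]
            k_vc: Dict[int, float] = defaultdict(float)
            for u, w in g.neighbors(v).items():
                k_vc[labels[u]] += w

            # detach v from its community
            sigma_tot[c_old] -= s_v
            sigma_in[c_old] -= 2.0 * k_vc.get(c_old, 0.0) + 2.0 * loop_v

            def gain(c: int) -> float:
                # Delta Q of attaching v (as a lone node) to community c,
                # relative to leaving it in a singleton of its own.
                return k_vc.get(c, 0.0) / m - sigma_tot[c] * s_v / (2.0 * m * m)

            stay_gain = gain(c_old)
            best_c, best_gain = c_old, stay_gain
            for c in sorted(k_vc):
                if c == c_old:
                    continue
                g_c = gain(c)
                # strict improvement required to leave c_old (MIN_GAIN guard);
                # among equally best true candidates, smallest label wins
                # because labels are visited in ascending order.
                if g_c > best_gain + MIN_GAIN:
                    best_c, best_gain = c, g_c

            # reattach
            sigma_tot[best_c] += s_v
            sigma_in[best_c] += 2.0 * k_vc.get(best_c, 0.0) + 2.0 * loop_v
            labels[v] = best_c
            if best_c != c_old:
                improved = True
                q += best_gain - stay_gain
                if on_move is not None:
                    on_move(g, dict(labels), q)
    return Partition(labels)


def aggregate(
    g: WeightedGraph, p: Partition
) -> Tuple[WeightedGraph, Dict[Label, int]]:
    """Collapse each community into a supernode.

    Returns the aggregated graph plus the mapping community label ->
    supernode id.  Inter-supernode edges carry the total weight between the
    two communities; each supernode's self-loop carries the total
    intra-community weight (member self-loops included).  Total weight m is
    conserved exactly.
    """
    p.validate_for(g)
    blocks = sorted(p.blocks().items(), key=lambda kv: min(map(str, kv[1])))
    super_of: Dict[Label, int] = {label: i for i, (label, _) in enumerate(blocks)}
    assignment = p._assignment

    inter: Dict[Tuple[int, int], float] = defaultdict(float)
    intra: Dict[int, float] = defaultdict(float)
    agg = WeightedGraph()
    for i in range(len(blocks)):
        agg.add_node(i)
    for u, v, w in g.edges():
        cu, cv = super_of[assignment[u]], super_of[assignment[v]]
        if cu == cv:
            intra[cu] += w
        else:
            key = (cu, cv) if cu < cv else (cv, cu)
            inter[key] += w
    for (cu, cv), w in inter.items():
        agg.add_edge(cu, cv, w)
    for c, w in intra.items():
        agg.add_edge(c, c, w)
    return agg, super_of


def louvain(
    g: WeightedGraph,
    init: Optional[Partition] = None,
    rng_seed: Optional[int] = None,
    *,
    shuffle: bool = True,
    on_move: Optional[MoveCallback] = None,
) -> Partition:
    """Full Louvain: local moves + aggregation until Q stops increasing.

    ``init`` is honored as the starting partition of the original graph
    (defaulting to singletons).  The returned partition is flat (labels on
    the original nodes), with ``Q(result) >= Q(init)``, and is reproducible
    for a fixed ``rng_seed``.
    """
    if g.total_weight() <= 0.0:
        raise ValidationError("louvain undefined for a graph with zero total weight")
    if init is None:
        init = Partition.singletons(g.nodes)
    init.validate_for(g)
    rng = random.Random(rng_seed)

    level_graph = g
    level_partition = init
    # flat[v] = node of the current level graph that original node v sits in
    flat: Dict[Node, Label] = {v: v for v in g.nodes}

    while True:
        q_before = modularity(level_graph, level_partition)
        moved = local_move_phase(
            level_graph, level_partition, rng=rng, shuffle=shuffle, on_move=on_move
        )
        q_after = modularity(level_graph, moved)
        agg, super_of = aggregate(level_graph, moved)
        assignment = moved._assignment
        flat = {v: super_of[assignment[flat[v]]] for v in flat}
        if q_after - q_before <= MIN_GAIN:
            break
        level_graph = agg
        level_partition = Partition.singletons(agg.nodes)

    return Partition(flat)
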