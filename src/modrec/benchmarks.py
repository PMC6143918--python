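"""Synthetic planted-partition networks and partition comparison.

These generators provide ground-truth community structure so the whole
pipeline is testable without any external dataset: flat planted partitions
(each intra-block pair is an edge with probability ``p_in``, inter-block
with ``p_out``) and a nested two-level variant whose tight sub-blocks hide
inside looser super-blocks — the situation the recursive extraction is
designed to resolve.

``nmi`` is the normalized mutual information between two partitions,
normalized by the arithmetic mean of the block-label entropies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .graph import WeightedGraph
from .louvain import Partition


@dataclass
class PlantedNetwork:
    """A generated graph bundled with its ground-truth partition."""

    graph: WeightedGraph
    truth: Partition
    params: dict
    #: coarse (super-block) truth for nested generators, else None
    truth_coarse: Optional[Partition] = None


def _node_name(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def _validate_weight_range(weight_low: float, weight_high: float) -> None:
    if not (0.0 <= weight_low <= weight_high <= 1.0):
        raise ValidationError(
            f"weight range must satisfy 0 <= low <= high <= 1, "
            f"got [{weight_low}, {weight_high}]"
        )


def _draw_weight(rng: np.random.Generator, low: float, high: float) -> float:
    if low == high:
        return low
    return float(rng.uniform(low, high))


def planted_partition(
    block_sizes: Sequence[int],
    p_in: float,
    p_out: float,
    weight_low: float = 1.0,
    weight_high: float = 1.0,
    seed: int = 0,
) -> PlantedNetwork:
    """Flat planted-partition graph with uniform edge weights.

    Every intra-block node pair becomes an edge with probability ``p_in``
    and every inter-block pair with probability ``p_out``; weights are drawn
    uniformly from ``[weight_low, weight_high]``.  Fully reproducible from
    ``seed``.
    """
    if not all(s >= 1 for s in block_sizes):
        raise ValidationError("block sizes must be >= 1")
    for name, p in (("p_in", p_in), ("p_out", p_out)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name} must be a probability, got {p}")
    _validate_weight_range(weight_low, weight_high)

    n = sum(block_sizes)
    width = max(4, len(str(n)))
    rng = np.random.default_rng(seed)

    block_of: Dict[str, int] = {}
    idx = 0
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            block_of[_node_name(idx, width)] = b
            idx += 1

    g = WeightedGraph()
    names = [_node_name(i, width) for i in range(n)]
    for v in names:
        g.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if block_of[names[i]] == block_of[names[j]] else p_out
            if p > 0.0 and rng.random() < p:
                g.add_edge(names[i], names[j], _draw_weight(rng, weight_low, weight_high))

    truth = Partition(block_of)
    params = {
        "generator": "planted_partition",
        "block_sizes": list(block_sizes),
        "p_in": p_in,
        "p_out": p_out,
        "weight_low": weight_low,
        "weight_high": weight_high,
        "seed": seed,
    }
    return PlantedNetwork(graph=g, truth=truth, params=params)


def nested_planted(
    super_blocks: int,
    sub_blocks_per: int,
    sub_size: int,
    p_sub: float,
    p_super: float,
    p_bg: float,
    seed: int = 0,
    weight_low: float = 1.0,
    weight_high: float = 1.0,
) -> PlantedNetwork:
    """Two-level planted structure: tight sub-blocks inside super-blocks.

    Edge probabilities are three-tier: ``p_sub`` within a sub-block,
    ``p_super`` between sub-blocks of the same super-block, ``p_bg`` across
    super-blocks.  The returned ``truth`` is the fine (sub-block) partition;
    ``truth_coarse`` carries the super-block level.  Requires
    ``p_sub >= p_super >= p_bg`` (equality collapses tiers).
    """
    if not (0.0 <= p_bg <= p_super <= p_sub <= 1.0):
        raise ValidationError(
            "tier probabilities must satisfy 0 <= p_bg <= p_super <= p_sub <= 1, "
            f"got p_sub={p_sub}, p_super={p_super}, p_bg={p_bg}"
        )
    if super_blocks < 1 or sub_blocks_per < 1 or sub_size < 1:
        raise ValidationError("block counts and sizes must be >= 1")
    _validate_weight_range(weight_low, weight_high)

    n = super_blocks * sub_blocks_per * sub_size
    width = max(4, len(str(n)))
    rng = np.random.default_rng(seed)

    fine: Dict[str, int] = {}
    coarse: Dict[str, int] = {}
    names: List[str] = []
    idx = 0
    for sb in range(super_blocks):
        for sub in range(sub_blocks_per):
            for _ in range(sub_size):
                name = _node_name(idx, width)
                names.append(name)
                fine[name] = sb * sub_blocks_per + sub
                coarse[name] = sb
                idx += 1

    g = WeightedGraph()
    for v in names:
        g.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            u, v = names[i], names[j]
            if fine[u] == fine[v]:
                p = p_sub
            elif coarse[u] == coarse[v]:
                p = p_super
            else:
                p = p_bg
            if p > 0.0 and rng.random() < p:
                g.add_edge(u, v, _draw_weight(rng, weight_low, weight_high))

    params = {
        "generator": "nested_planted",
        "super_blocks": super_blocks,
        "sub_blocks_per": sub_blocks_per,
        "sub_size": sub_size,
        "p_sub": p_sub,
        "p_super": p_super,
        "p_bg": p_bg,
        "weight_low": weight_low,
        "weight_high": weight_high,
        "seed": seed,
    }
    return PlantedNetwork(
        graph=g,
        truth=Partition(fine),
        params=params,
        truth_coarse=Partition(coarse),
    )


def nmi(p: Partition, q: Partition) -> float:
    """Normalized mutual information between two partitions of one node set.

    Normalization is by the arithmetic mean of the two label entropies:
    ``NMI = 2 I(P; Q) / (H(P) + H(Q))``.  Two trivial single-block
    partitions compare as 1 by convention; a trivial vs. non-trivial pair
    yields 0.
    """
    if p.nodes != q.nodes:
        raise ValidationError("partitions cover different node sets")
    n = len(p)
    if n == 0:
        raise ValidationError("partitions are empty")

    pa, qa = p._assignment, q._assignment
    joint: Dict[tuple, int] = {}
    pc: Dict[object, int] = {}
    qc: Dict[object, int] = {}
    for v in pa:
        a, b = pa[v], qa[v]
        joint[(a, b)] = joint.get((a, b), 0) + 1
        pc[a] = pc.get(a, 0) + 1
        qc[b] = qc.get(b, 0) + 1

    h_p = -sum((c / n) * math.log(c / n) for c in pc.values() if c > 0)
    h_q = -sum((c / n) * math.log(c / n) for c in qc.values() if c > 0)
    if h_p == 0.0 and h_q == 0.0:
        return 1.0
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * math.log(n * c / (pc[a] * qc[b]))
    value = 2.0 * mi / (h_p + h_q)
    # clamp tiny negative round-off
    return min(1.0, max(0.0, value))
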