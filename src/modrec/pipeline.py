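"""Top-level recursive module extraction and the submission-format writer.

A work list starts with the standardized input network.  For each network
popped off the list: weighted PageRank is computed, the seed partition is
built, and Louvain is run from that seed.  Each resulting community is then
routed by size: within [3, k] it is emitted as a module, below 3 it is
discarded, above k its induced subgraph goes back on the work list.  An
oversized community that Louvain cannot split (the result is the whole
subnetwork as one block) is discarded — the only policy that terminates and
never emits an invalid module.  Child RNG seeds are derived from the parent
seed and the push order, so a single seed reproduces the entire recursion.
"""

from __future__ import annotations

import os
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

from .errors import ValidationError
from .graph import Node, WeightedGraph, induced_subgraph
from .louvain import louvain
from .pagerank import seed_partition, weighted_pagerank

MIN_MODULE_SIZE = 3
MAX_K = 100


@dataclass
class ModuleSet:
    """Disjoint modules of 3..k nodes, ids assigned in emission order from 1."""

    modules: List[Tuple[int, FrozenSet[Node]]] = field(default_factory=list)
    #: module id -> recursion depth at which it was emitted
    provenance: Dict[int, int] = field(default_factory=dict)
    #: nodes never assigned to any module (too-small or unsplittable blocks)
    discarded_nodes: int = 0
    #: count of oversized communities Louvain could not split (discarded whole)
    unsplittable_discards: int = 0
    max_depth_reached: int = 0

    def members(self, module_id: int) -> FrozenSet[Node]:
        for mid, block in self.modules:
            if mid == module_id:
                return block
        raise KeyError(f"no module with id {module_id}")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def covered_nodes(self) -> FrozenSet[Node]:
        out: set = set()
        for _, block in self.modules:
            out |= block
        return frozenset(out)

    def sizes(self) -> List[int]:
        return [len(block) for _, block in self.modules]

    def depth_histogram(self) -> Dict[int, int]:
        return dict(Counter(self.provenance.values()))

    def report(self) -> dict:
        """JSON-ready run summary."""
        return {
            "module_count": len(self.modules),
            "module_sizes": self.sizes(),
            "depth_histogram": {str(d): c for d, c in sorted(self.depth_histogram().items())},
            "discarded_node_count": self.discarded_nodes,
            "unsplittable_discards": self.unsplittable_discards,
            "max_depth_reached": self.max_depth_reached,
        }


def _child_seed(parent_seed: int, depth: int, order: int) -> int:
    """Deterministic per-subnetwork seed derived from the recursion path."""
    ss = np.random.SeedSequence(entropy=parent_seed, spawn_key=(depth, order))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))


def extract_modules(
    g: WeightedGraph,
    k: int,
    rng_seed: int,
    max_depth: int = 50,
    *,
    damping: float = 0.85,
    pagerank_tol: float = 1e-9,
    pagerank_max_iter: int = 200,
) -> ModuleSet:
    """Recursively extract disjoint modules of size 3..k from ``g``.

    ``g`` is expected to be standardized already (undirected, weights in
    [0, 1]); see :mod:`modrec.preprocess`.  The result is reproducible for
    fixed ``(g, k, rng_seed)``.
    """
    if not (MIN_MODULE_SIZE <= k <= MAX_K):
        raise ValidationError(f"k must be in [{MIN_MODULE_SIZE}, {MAX_K}], got {k}")

    result = ModuleSet()
    work: deque = deque()
    work.append((g, 0, int(rng_seed)))
    next_id = 1

    while work:
        sub, depth, seed = work.popleft()
        result.max_depth_reached = max(result.max_depth_reached, depth)
        if depth > max_depth:
            warnings.warn(
                f"recursion depth exceeded max_depth={max_depth}; "
                f"dropping a {sub.number_of_nodes()}-node subnetwork",
                RuntimeWarning,
                stacklevel=2,
            )
            result.discarded_nodes += sub.number_of_nodes()
            continue
        if sub.total_weight() <= 0.0:
            # no edges left: every community would be a singleton
            result.discarded_nodes += sub.number_of_nodes()
            continue

        pr = weighted_pagerank(
            sub, damping=damping, tol=pagerank_tol, max_iter=pagerank_max_iter
        )
        init = seed_partition(sub, pr)
        partition = louvain(sub, init, rng_seed=seed)
        blocks = partition.block_list()

        if len(blocks) == 1 and blocks[0] == frozenset(sub.nodes):
            # Louvain could not split this network; emitting it would violate
            # the size cap (it only reaches here when > k or as the root)
            if len(blocks[0]) > k:
                result.unsplittable_discards += 1
                result.discarded_nodes += len(blocks[0])
                continue

        pushed = 0
        for block in blocks:
            size = len(block)
            if MIN_MODULE_SIZE <= size <= k:
                result.modules.append((next_id, block))
                result.provenance[next_id] = depth
                next_id += 1
            elif size < MIN_MODULE_SIZE:
                result.discarded_nodes += size
            else:
                work.append(
                    (
                        induced_subgraph(sub, block),
                        depth + 1,
                        _child_seed(seed, depth, pushed),
                    )
                )
                pushed += 1
    return result


def write_module_set(ms: ModuleSet, path: os.PathLike | str) -> None:
    """Write one line per module: ``<id>\\t1.0\\t<members...>``.

    Members are tab-joined in lexicographic order; modules appear in id
    order.  The constant ``1.0`` column is the submission-format confidence
    placeholder.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for mid, block in sorted(ms.modules):
            members = "\t".join(sorted(map(str, block)))
            fh.write(f"{mid}\t1.0\t{members}\n")


def read_module_set(path: os.PathLike | str) -> ModuleSet:
    """Round-trip reader for :func:`write_module_set` output."""
    ms = ModuleSet()
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed module line: {line!r}")
            mid = int(fields[0])
            ms.modules.append((mid, frozenset(fields[2:])))
    return ms
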