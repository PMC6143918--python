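# modrec

Recursive, size-constrained module extraction from weighted biological
networks. The pipeline:

1. **Standardize** the network: optionally convert a directed edge list to
   undirected (averaging the two arc weights of each pair) and normalize all
   weights into [0, 1] by dividing by the maximum.
2. **Seed**: compute an edge-weight-aware PageRank and build an initial
   partition in which each node joins its highest-scoring neighbor (or stays
   alone if no neighbor outscores it).
3. **Cluster**: run Louvain modularity optimization (Newman–Girvan
   criterion) starting from that seed partition instead of singletons.
4. **Recurse**: communities of 3..k nodes are emitted as modules, smaller
   ones discarded, larger ones extracted as subnetworks and re-processed
   (fresh PageRank + Louvain per subnetwork) until the work list is empty.

Oversized communities that Louvain cannot split are discarded, which
guarantees termination (e.g. on complete graphs). A single seed makes the
whole recursion byte-reproducible.

## CLI

```bash
# extract modules from a tab-separated edge list (node_a  node_b  weight)
modrec run --input network.tsv --k 100 --seed 1 --output modules.tsv
# directed input + weight normalization
modrec run --input signalling.tsv --directed --normalize --k 50 \
    --seed 1 --output modules.tsv

# preprocessing alone
modrec preprocess --input signalling.tsv --directed --normalize \
    --output standardized.tsv

# synthetic benchmarks with ground truth (flat or nested planted partition)
modrec simulate --blocks 32,32,32,32 --p-in 0.45 --p-out 0.02 --seed 7 \
    --out-edges bench.tsv --out-truth truth.tsv
modrec simulate --nested --super-blocks 4 --sub-blocks-per 2 --sub-size 10 \
    --seed 7 --out-edges nested.tsv --out-truth truth.tsv
```

`modrec run` writes one line per module (`<id>\t1.0\t<members...>`) plus a
JSON run report (`<output>.report.json`) with module sizes, the recursion
depth histogram and discard counts.

## Library

```python
from modrec import (
    read_edge_list, to_undirected, normalize_weights,
    weighted_pagerank, seed_partition, louvain, modularity,
    extract_modules, nested_planted, nmi,
)

net = nested_planted(4, 2, 10, p_sub=0.9, p_super=0.3, p_bg=0.01, seed=1)
modules = extract_modules(net.graph, k=15, rng_seed=1)
```

## Layout

- `src/modrec/graph.py` — weighted graph model, edge-list I/O
- `src/modrec/preprocess.py` — directed→undirected averaging, normalization
- `src/modrec/pagerank.py` — weighted PageRank, seed partition
- `src/modrec/louvain.py` — modularity, local moves, aggregation, Louvain
- `src/modrec/pipeline.py` — recursive extraction, submission-format writer
- `src/modrec/benchmarks.py` — planted/nested generators, NMI
- `src/modrec/cli.py` — `modrec run | preprocess | simulate`
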