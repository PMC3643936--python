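"""Subgraph extraction, cohesion validation and density measures.

Each part of a k-way partition yields at most one candidate subgraph: the
largest connected component of the part's induced subgraph, kept only if it
has more than two nodes. Candidates are de-duplicated on their gene set
across the whole multi-resolution run. Because the partitioner always splits
the entire graph, a candidate may be an artefact of the requested k rather
than a genuine locality; candidates are therefore validated by comparing the
mean shortest-path distance inside the subgraph against the mean distances to
every other subgraph of the same partition with a one-tailed one-sample
t-test, discarding subgraphs whose internal cohesion is not significantly
tighter.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from modulenet.netio import Network
from modulenet.stats import one_sample_t_greater


@dataclass
class Subgraph:
    """A connected gene set induced from one part of one partition."""

    id: str
    source_layer: str
    genes: frozenset
    graph: nx.Graph
    k_origin: tuple = ()
    validation_p: float | None = None

    def __post_init__(self):
        if len(self.genes) < 3:
            raise ValueError("subgraphs must contain more than two nodes")
        if set(self.graph.nodes) != set(self.genes):
            raise ValueError("induced graph nodes must equal the gene set")
        if not nx.is_connected(self.graph):
            raise ValueError("subgraphs must be connected")

    def size(self) -> int:
        return len(self.genes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sum_weight(self) -> float:
        return float(sum(d.get("weight", 1.0) for _, _, d in self.graph.edges(data=True)))


def extract_subgraphs(network: Network, partition, min_nodes: int = 3,
                      id_prefix: str | None = None) -> list[Subgraph]:
    """Largest connected component per part, dropping components with fewer
    than ``min_nodes`` nodes; duplicate gene sets within the partition are
    collapsed to one."""
    prefix = id_prefix if id_prefix is not None else f"{network.layer_name}:k{partition.k}"
    seen: dict[frozenset, Subgraph] = {}
    out = []
    for idx, members in enumerate(partition.parts()):
        if len(members) < min_nodes:
            continue
        induced = network.graph.subgraph(members)
        components = list(nx.connected_components(induced))
        if not components:
            continue
        # deterministic LCC choice: max size, ties by sorted gene tuple
        lcc = max(components, key=lambda c: (len(c), tuple(sorted(c, key=str))))
        if len(lcc) < min_nodes:
            continue
        genes = frozenset(lcc)
        if genes in seen:
            continue
        sub = Subgraph(
            id=f"{prefix}:p{idx}",
            source_layer=network.layer_name,
            genes=genes,
            graph=network.graph.subgraph(lcc).copy(),
            k_origin=(partition.k,),
        )
        seen[genes] = sub
        out.append(sub)
    return out


def dedupe_subgraphs(subgraphs: list[Subgraph]) -> list[Subgraph]:
    """Collapse identical gene sets produced at different k, merging the
    k-of-origin provenance; first-seen id wins."""
    by_genes: dict[frozenset, Subgraph] = {}
    for sub in subgraphs:
        prev = by_genes.get(sub.genes)
        if prev is None:
            by_genes[sub.genes] = sub
        else:
            ks = tuple(sorted(set(prev.k_origin) | set(sub.k_origin)))
            prev.k_origin = ks
    return list(by_genes.values())


def _edge_lengths(network: Network):
    """Dijkstra edge lengths: 1 on unweighted layers, 1/weight on weighted
    layers so that strongly linked pairs are close."""
    nodes = sorted(network.graph.nodes, key=str)
    index = {node: i for i, node in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in network.graph.edges(data=True):
        length = 1.0 / d["weight"] if network.weighted else 1.0
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [length, length]
    mat = csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return nodes, index, mat


def all_pairs_distances(network: Network, nodes=None):
    """Shortest-path distances from each listed node to every network node.

    Returns (node_index, source_nodes, matrix); unreachable pairs are inf.
    """
    all_nodes, index, mat = _edge_lengths(network)
    if nodes is None:
        sources = all_nodes
    else:
        missing = [n for n in nodes if n not in index]
        if missing:
            raise KeyError(f"nodes not in network: {missing[:5]}")
        sources = sorted(nodes, key=str)
    src_idx = np.array([index[n] for n in sources], dtype=np.int64)
    dist = dijkstra(mat, directed=False, indices=src_idx)
    return index, sources, dist


class DistanceCache:
    """Full all-pairs distance matrix of one network, shared across the
    validation of every partition of that network."""

    def __init__(self, network: Network):
        self.index, _, self.dist = all_pairs_distances(network)

    def mean_between(self, genes_a, genes_b) -> float:
        ia = np.fromiter((self.index[g] for g in genes_a), dtype=np.int64)
        ib = np.fromiter((self.index[g] for g in genes_b), dtype=np.int64)
        block = self.dist[np.ix_(ia, ib)]
        finite = np.isfinite(block)
        if not finite.any():
            return np.nan
        return float(block[finite].mean())

    def mean_intra(self, genes) -> float:
        ia = np.fromiter((self.index[g] for g in genes), dtype=np.int64)
        block = self.dist[np.ix_(ia, ia)]
        off = ~np.eye(len(ia), dtype=bool)
        finite = np.isfinite(block) & off
        if not finite.any():
            return np.nan
        return float(block[finite].mean())


def validate_subgraph(subgraph: Subgraph, cohort: list[Subgraph],
                      network: Network, alpha: float = 0.05,
                      cache: DistanceCache | None = None) -> float | None:
    """One-tailed one-sample t-test of the per-neighbour mean inter-subgraph
    distances against the mean intra-subgraph distance (alternative:
    intra < inter). Returns the p-value, or None (not applicable) when fewer
    than two other subgraphs provide a finite inter mean. The pipeline
    discards subgraphs with p >= alpha and keeps not-applicable ones flagged.
    """
    others = [s for s in cohort if s.genes != subgraph.genes]
    if len(others) < 2:
        return None
    if cache is None:
        cache = DistanceCache(network)
    intra = cache.mean_intra(subgraph.genes)
    if not np.isfinite(intra):
        return None
    inter = [cache.mean_between(subgraph.genes, o.genes) for o in others]
    inter = [m for m in inter if np.isfinite(m)]
    if len(inter) < 2:
        return None
    return one_sample_t_greater(inter, intra)


def validation_pvalues(cohort: list[Subgraph], cache: DistanceCache) -> list[float | None]:
    """Vectorised :func:`validate_subgraph` over a whole partition cohort.

    Computes every intra- and inter-subgraph mean distance with two matrix
    products instead of per-pair indexing; results match validate_subgraph
    exactly.
    """
    m = len(cohort)
    if m < 3:
        return [None] * m
    n = cache.dist.shape[0]
    finite = np.isfinite(cache.dist)
    dfin = np.where(finite, cache.dist, 0.0)
    z = np.zeros((m, n))
    sizes = np.zeros(m)
    for a, sub in enumerate(cohort):
        for g in sub.genes:
            z[a, cache.index[g]] = 1.0
        sizes[a] = len(sub.genes)
    sums = z @ dfin @ z.T
    counts = z @ finite.astype(float) @ z.T
    out: list[float | None] = []
    for a in range(m):
        intra_count = counts[a, a] - sizes[a]  # self-pairs are finite zeros
        if intra_count <= 0:
            out.append(None)
            continue
        intra = sums[a, a] / intra_count
        inter = []
        for b in range(m):
            if b == a or counts[a, b] == 0:
                continue
            inter.append(sums[a, b] / counts[a, b])
        if len(inter) < 2:
            out.append(None)
        else:
            out.append(one_sample_t_greater(inter, intra))
    return out


def edge_density(subgraph: Subgraph) -> float:
    """d = 2e / (n(n-1)): fraction of possible gene pairs that interact."""
    n = subgraph.size()
    if n < 2:
        raise ValueError("edge density needs at least two nodes")
    return 2.0 * subgraph.n_edges() / (n * (n - 1))


def weighted_density(subgraph: Subgraph, network_mean_weight: float) -> float:
    """h = 2w / (mean_w * n(n-1)); reduces to edge density when every edge
    weight equals the network mean."""
    if network_mean_weight <= 0:
        raise ValueError("network mean edge weight must be positive")
    n = subgraph.size()
    if n < 2:
        raise ValueError("weighted density needs at least two nodes")
    return 2.0 * subgraph.sum_weight() / (network_mean_weight * n * (n - 1))
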