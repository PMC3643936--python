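"""Cross-network subgraph congruence.

Subgraphs from different networks whose gene sets intersect more than chance
predicts are *congruent*. Each candidate pair is scored with a 2x2 confusion
table (TP = intersection, FP/FN = each subgraph minus the intersection,
TN = union minus intersection, following the congruence definition) and the
Matthews correlation coefficient; significance is an upper-tail
hypergeometric (Fisher) test, Benjamini-Hochberg corrected over all computed
tests. For each subgraph, its maximal-MCC significant intersection per
opposing network is its *best hit*; mutual best hits are *reciprocal best
hits*, the strongest evidence that two networks found the same functional
module. Best hits form a graph over subgraphs whose unusually high-degree
nodes (plus their neighbours) are the *high-degree neighbourhoods*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix

from modulenet import stats
from modulenet.netio import Network
from modulenet.subgraphs import Subgraph


@dataclass(frozen=True)
class OverlapCounts:
    """Confusion counts of a subgraph pair: tn follows the congruence
    definition (union minus intersection, i.e. fp + fn)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_gene_sets(cls, a, b) -> "OverlapCounts":
        tp = len(a & b)
        fp = len(a) - tp
        fn = len(b) - tp
        return cls(tp=tp, fp=fp, fn=fn, tn=fp + fn)


def mcc(counts) -> float:
    """MCC of an overlap table; accepts OverlapCounts or (tp, fp, fn, tn).

    Identical gene sets are a special case: with tn defined as the union
    minus the intersection, perfect agreement forces tn = 0 and the table
    degenerates; the perfect-agreement limit 1.0 is returned (rather than
    the generic zero-denominator convention of 0, which would rank an exact
    match as the worst possible hit).
    """
    if isinstance(counts, OverlapCounts):
        tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    else:
        tp, fp, fn, tn = counts
    if tp > 0 and fp == 0 and fn == 0 and tn == 0:
        return 1.0
    return stats.mcc(tp, fp, fn, tn)


@dataclass
class CongruenceHit:
    """A scored intersection between subgraphs of two different networks."""

    subgraph_a: str
    subgraph_b: str
    layer_a: str
    layer_b: str
    size_a: int
    size_b: int
    counts: OverlapCounts
    mcc: float
    p: float
    q: float | None = None
    best_a_to_b: bool = False
    best_b_to_a: bool = False

    def is_reciprocal(self) -> bool:
        return self.best_a_to_b and self.best_b_to_a


def overlap_test(a: Subgraph, b: Subgraph, universe: set,
                 n_min: int = 3, m_min: float = 0.2, max_ratio: float = 10.0,
                 mode: str = "network_union") -> CongruenceHit | None:
    """Score one subgraph pair; returns None when a pre-filter rejects it.

    Pre-filters: the two gene-set sizes may differ at most ``max_ratio``-fold,
    the intersection must reach ``n_min`` genes and the MCC must reach
    ``m_min`` before a p-value is computed. The hypergeometric population is
    the union of the two source networks' gene sets (``mode='network_union'``)
    or, for fidelity with the literal construction, the union of the two
    subgraphs (``mode='literal_union'``, in which the test is degenerate).
    """
    if a.source_layer == b.source_layer:
        raise ValueError("congruence is defined between different networks")
    big, small = max(a.size(), b.size()), min(a.size(), b.size())
    if big / small > max_ratio:
        return None
    counts = OverlapCounts.from_gene_sets(a.genes, b.genes)
    if counts.tp < n_min:
        return None
    score = mcc(counts)
    if score < m_min:
        return None
    union_size = len(a.genes | b.genes)
    if mode == "network_union":
        m = len(universe)
        if m < union_size:
            raise ValueError("universe smaller than the union of the subgraphs")
    elif mode == "literal_union":
        m = union_size
    else:
        raise ValueError(f"unknown universe mode {mode!r}")
    p = stats.hypergeom_sf(counts.tp, m, a.size(), b.size())
    return CongruenceHit(
        subgraph_a=a.id, subgraph_b=b.id,
        layer_a=a.source_layer, layer_b=b.source_layer,
        size_a=a.size(), size_b=b.size(),
        counts=counts, mcc=score, p=p,
    )


def score_layer_pair(subs_a: list[Subgraph], subs_b: list[Subgraph],
                     universe: set, n_min: int = 3, m_min: float = 0.2,
                     max_ratio: float = 10.0,
                     mode: str = "network_union") -> list[CongruenceHit]:
    """Vectorised overlap_test over all subgraph pairs of two networks."""
    if not subs_a or not subs_b:
        return []
    subs_a = sorted(subs_a, key=lambda s: s.id)
    subs_b = sorted(subs_b, key=lambda s: s.id)
    genes = sorted(universe, key=str)
    gidx = {g: i for i, g in enumerate(genes)}

    def incidence(subs):
        rows, cols = [], []
        for i, s in enumerate(subs):
            for g in s.genes:
                rows.append(i)
                cols.append(gidx[g])
        return csr_matrix((np.ones(len(rows), dtype=np.int64), (rows, cols)),
                          shape=(len(subs), len(genes)))

    A, B = incidence(subs_a), incidence(subs_b)
    tp = np.asarray((A @ B.T).todense(), dtype=np.int64)
    sa = np.array([s.size() for s in subs_a], dtype=np.int64)[:, None]
    sb = np.array([s.size() for s in subs_b], dtype=np.int64)[None, :]
    ratio_ok = (np.maximum(sa, sb) / np.minimum(sa, sb)) <= max_ratio
    fp = sa - tp
    fn = sb - tp
    score = stats.mcc_array(tp, fp, fn, fp + fn)
    score[(tp > 0) & (fp == 0) & (fn == 0)] = 1.0  # identical sets
    mask = ratio_ok & (tp >= n_min) & (score >= m_min)
    ii, jj = np.nonzero(mask)
    if mode == "literal_union":
        m_pop = (sa + sb - tp)[ii, jj]
    else:
        m_pop = len(genes)
    pvals = stats.hypergeom_sf_array(tp[ii, jj], m_pop, sa[ii, 0], sb[0, jj])
    pvals = np.atleast_1d(pvals)
    hits = []
    for idx in range(len(ii)):
        i, j = int(ii[idx]), int(jj[idx])
        counts = OverlapCounts(tp=int(tp[i, j]), fp=int(fp[i, j]),
                               fn=int(fn[i, j]), tn=int(fp[i, j] + fn[i, j]))
        hits.append(CongruenceHit(
            subgraph_a=subs_a[i].id, subgraph_b=subs_b[j].id,
            layer_a=subs_a[i].source_layer, layer_b=subs_b[j].source_layer,
            size_a=int(sa[i, 0]), size_b=int(sb[0, j]),
            counts=counts, mcc=float(score[i, j]), p=float(pvals[idx]),
        ))
    return hits


def call_best_hits(hits: list[CongruenceHit], fdr_alpha: float = 0.05) -> list[CongruenceHit]:
    """BH-correct all computed tests, then flag, per subgraph and opposing
    network, the significant hit with maximal MCC (ties: smaller q, then
    lexicographic partner id). Returns the hits with q and flags set."""
    if not hits:
        return hits
    hits = sorted(hits, key=lambda h: (h.subgraph_a, h.subgraph_b))
    q = stats.bh_qvalues([h.p for h in hits])
    for h, qv in zip(hits, q):
        h.q = float(qv)
        h.best_a_to_b = False
        h.best_b_to_a = False
    best: dict[tuple, CongruenceHit] = {}

    def consider(key, hit, partner_id):
        cur = best.get(key)
        if cur is None:
            best[key] = hit
            return
        cur_partner = cur.subgraph_b if key[2] == "a" else cur.subgraph_a
        if (-hit.mcc, hit.q, partner_id) < (-cur.mcc, cur.q, cur_partner):
            best[key] = hit

    for h in hits:
        if h.q >= fdr_alpha:
            continue
        consider((h.subgraph_a, h.layer_b, "a"), h, h.subgraph_b)
        consider((h.subgraph_b, h.layer_a, "b"), h, h.subgraph_a)
    for key, h in best.items():
        if key[2] == "a":
            h.best_a_to_b = True
        else:
            h.best_b_to_a = True
    return hits


def reciprocal_best_hits(hits: list[CongruenceHit]) -> list[CongruenceHit]:
    return [h for h in hits if h.is_reciprocal()]


def build_best_hit_graph(hits: list[CongruenceHit]) -> nx.Graph:
    """Graph over subgraph ids; one edge per best hit (either direction)."""
    g = nx.Graph()
    for h in sorted(hits, key=lambda h: (h.subgraph_a, h.subgraph_b)):
        if not (h.best_a_to_b or h.best_b_to_a):
            continue
        g.add_node(h.subgraph_a, layer=h.layer_a)
        g.add_node(h.subgraph_b, layer=h.layer_b)
        g.add_edge(h.subgraph_a, h.subgraph_b, mcc=h.mcc, q=h.q,
                   reciprocal=h.is_reciprocal())
    return g


def high_degree(graph: nx.Graph, percentile: float = 97.5) -> list[str]:
    """Subgraphs whose best-hit degree exceeds the upper percentile cutoff."""
    if graph.number_of_nodes() == 0:
        return []
    nodes = sorted(graph.nodes, key=str)
    degrees = np.array([graph.degree(n) for n in nodes], dtype=float)
    cutoff = np.percentile(degrees, percentile)
    return [n for n, d in zip(nodes, degrees) if d > cutoff]


def high_degree_neighbourhoods(graph: nx.Graph, hd_nodes: list[str]) -> set:
    """High-degree subgraphs together with all their best-hit partners."""
    members = set()
    for n in hd_nodes:
        members.add(n)
        members |= set(graph.neighbors(n))
    return members


@dataclass
class MergedSubnetwork:
    """Union of a reciprocal-best-hit pair with per-layer edge provenance and
    unit-length node/edge betweenness."""

    id: str
    subgraph_a: str
    subgraph_b: str
    genes: frozenset
    graph: nx.Graph
    node_betweenness: dict = field(default_factory=dict)
    edge_betweenness: dict = field(default_factory=dict)


def merge_subgraphs(a: Subgraph, b: Subgraph, layers: list[Network],
                    hit: CongruenceHit) -> MergedSubnetwork:
    """Merge a reciprocal best hit into one subnetwork.

    Node set is the union of the two gene sets; the edge set is the union of
    every layer's induced edges over those genes, tagged with the
    contributing layers. Betweenness uses unit edge lengths.
    """
    if {a.id, b.id} != {hit.subgraph_a, hit.subgraph_b} or not hit.is_reciprocal():
        raise ValueError("merge_subgraphs requires the pair's reciprocal best hit")
    genes = a.genes | b.genes
    g = nx.Graph()
    g.add_nodes_from(sorted(genes, key=str))
    for layer in layers:
        induced = layer.graph.subgraph(genes & layer.nodes)
        for u, v in induced.edges():
            if g.has_edge(u, v):
                g[u][v]["layers"] = tuple(sorted(set(g[u][v]["layers"]) | {layer.layer_name}))
            else:
                g.add_edge(u, v, layers=(layer.layer_name,))
    node_bc = nx.betweenness_centrality(g, normalized=False)
    edge_bc = nx.edge_betweenness_centrality(g, normalized=False)
    return MergedSubnetwork(
        id=f"merge:{a.id}|{b.id}",
        subgraph_a=a.id, subgraph_b=b.id,
        genes=frozenset(genes), graph=g,
        node_betweenness={n: float(v) for n, v in node_bc.items()},
        edge_betweenness={tuple(sorted(e, key=str)): float(v) for e, v in edge_bc.items()},
    )
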