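"""Network data model and edge-list I/O.

Networks are labelled undirected gene-interaction graphs. The on-disk dialect
is a plain-text edge list whose first (non-comment) line is the number of
edges, followed by one whitespace-separated node pair per line, with an
optional third weight column for weighted layers. A separate two-column
lookup table maps integer node identifiers to systematic gene names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx


class NetworkFormatError(ValueError):
    """Raised when an edge-list file violates the dialect contract."""


@dataclass
class Network:
    """An undirected gene-interaction layer.

    Edges carry a positive ``weight`` attribute (1.0 throughout for
    unweighted layers) and may carry an integer ``iweight`` used as the
    partitioning objective. Self-loops are rejected.
    """

    layer_name: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    weighted: bool = False

    @classmethod
    def from_edges(
        cls,
        layer_name: str,
        edges: Iterable[tuple],
        weighted: bool = False,
        nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from (u, v) or (u, v, weight) tuples."""
        g = nx.Graph()
        for node in nodes:
            g.add_node(node)
        for edge in edges:
            if len(edge) == 3:
                u, v, w = edge
            else:
                u, v = edge
                w = 1.0
            w = float(w)
            if u == v:
                raise NetworkFormatError(f"self-loop on node {u!r}")
            if w <= 0 or not math.isfinite(w):
                raise NetworkFormatError(f"non-positive weight {w!r} on edge ({u}, {v})")
            if g.has_edge(u, v):
                raise NetworkFormatError(f"duplicate edge ({u}, {v})")
            g.add_edge(u, v, weight=w)
        return cls(layer_name=layer_name, graph=g, weighted=weighted)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def mean_edge_weight(self) -> float:
        e = self.n_edges()
        if e == 0:
            raise ValueError(f"layer {self.layer_name!r} has no edges")
        return self.total_weight() / e

    def sorted_edges(self) -> list[tuple]:
        """Edges as (u, v, weight) with u < v, lexicographically sorted."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = (u, v) if str(u) <= str(v) else (v, u)
            out.append((a, b, d["weight"]))
        out.sort(key=lambda t: (str(t[0]), str(t[1])))
        return out


@dataclass
class GeneLookup:
    """Bijective mapping between integer node identifiers and gene names."""

    id_to_name: dict

    def __post_init__(self):
        names = list(self.id_to_name.values())
        if len(set(names)) != len(names):
            raise ValueError("lookup is not bijective: duplicate gene names")
        self.name_to_id = {v: k for k, v in self.id_to_name.items()}

    @classmethod
    def read_tsv(cls, path) -> "GeneLookup":
        mapping = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                ident, name = line.split()[:2]
                if ident in mapping:
                    raise NetworkFormatError(f"duplicate id {ident!r} in lookup")
                mapping[ident] = name
        return cls(mapping)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for ident in sorted(self.id_to_name, key=str):
                fh.write(f"{ident}\t{self.id_to_name[ident]}\n")

    def rename(self, network: Network) -> Network:
        """Return a copy of ``network`` with node ids replaced by gene names."""
        missing = [n for n in network.graph.nodes if n not in self.id_to_name]
        if missing:
            raise KeyError(f"nodes without a lookup entry: {missing[:5]}")
        g = nx.relabel_nodes(network.graph, self.id_to_name, copy=True)
        return Network(network.layer_name, g, network.weighted)


def _format_weight(w: float) -> str:
    # repr round-trips floats bit-exactly; integers stay compact
    return repr(w) if w != int(w) else str(int(w))


def read_edge_list(path, weighted: bool = False, layer_name: str | None = None) -> Network:
    """Read an edge list in the header-count dialect.

    The first non-comment line declares the edge count; each subsequent line
    holds two node fields plus, for ``weighted`` files, a numeric weight.
    Declared-count mismatches, self-loops, duplicate unordered pairs and
    non-numeric weights are format errors.
    """
    path = Path(path)
    name = layer_name if layer_name is not None else path.stem
    g = nx.Graph()
    declared = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if declared is None:
                try:
                    declared = int(line)
                except ValueError:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: first line must be the edge count, got {line!r}"
                    ) from None
                if declared < 0:
                    raise NetworkFormatError(f"{path}: negative edge count {declared}")
                continue
            fields = line.split()
            expected = 3 if weighted else 2
            if len(fields) != expected:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected {expected} fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if u == v:
                raise NetworkFormatError(f"{path}:{lineno}: self-loop on {u!r}")
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
                if w <= 0 or not math.isfinite(w):
                    raise NetworkFormatError(f"{path}:{lineno}: non-positive weight {w}")
            else:
                w = 1.0
            if g.has_edge(u, v):
                raise NetworkFormatError(f"{path}:{lineno}: duplicate edge ({u}, {v})")
            g.add_edge(u, v, weight=w)
    if declared is None:
        raise NetworkFormatError(f"{path}: missing edge-count header")
    if g.number_of_edges() != declared:
        raise NetworkFormatError(
            f"{path}: header declares {declared} edges, file contains "
            f"{g.number_of_edges()}"
        )
    return Network(name, g, weighted)


def write_edge_list(network: Network, path) -> Path:
    """Write a network in the header-count dialect (sorted, deterministic).

    Weighted layers emit a third column whose textual form round-trips
    bit-exactly through :func:`read_edge_list`.
    """
    path = Path(path)
    edges = network.sorted_edges()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(edges)}\n")
        for u, v, w in edges:
            if network.weighted:
                fh.write(f"{u} {v} {_format_weight(w)}\n")
            else:
                fh.write(f"{u} {v}\n")
    return path


def combine_networks(layers: Sequence[Network], layer_total: float = 1.0,
                     name: str = "combined") -> Network:
    """Weighted union of layers with per-layer weight normalisation.

    Each layer's weights are rescaled so that the layer contributes the same
    total weight (``layer_total``, default 1.0) to the union; a combined
    edge's weight is the sum of the rescaled weights over the layers that
    contain it.
    """
    if len(layers) < 2:
        raise ValueError("combine_networks needs at least two layers")
    g = nx.Graph()
    for layer in layers:
        tot = layer.total_weight()
        if tot <= 0:
            raise ValueError(f"layer {layer.layer_name!r} has zero total weight")
        scale = layer_total / tot
        for node in layer.graph.nodes:
            g.add_node(node)
        for u, v, d in layer.graph.edges(data=True):
            w = d["weight"] * scale
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
                g[u][v]["layers"] = g[u][v]["layers"] + (layer.layer_name,)
            else:
                g.add_edge(u, v, weight=w, layers=(layer.layer_name,))
    return Network(name, g, weighted=True)


def common_gene_networks(layers: Sequence[Network], scope: str = "per_layer") -> list[Network]:
    """Restrict every layer to the genes present in all layers.

    After inducing each layer on the common gene set, nodes left without any
    edge are removed: per layer independently (``scope='per_layer'``), or from
    every layer if isolated in any one of them (``scope='global'``).
    """
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    if scope not in ("per_layer", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    common = set.intersection(*(layer.nodes for layer in layers))
    if not common:
        raise ValueError("gene intersection of the layers is empty")
    induced = []
    for layer in layers:
        sub = layer.graph.subgraph(common).copy()
        induced.append(sub)
    if scope == "global":
        dropped = set()
        for sub in induced:
            dropped |= {n for n in sub.nodes if sub.degree(n) == 0}
        for sub in induced:
            sub.remove_nodes_from(dropped & set(sub.nodes))
    out = []
    for layer, sub in zip(layers, induced):
        sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
        out.append(Network(layer.layer_name, sub, layer.weighted))
    return out


def assign_integer_weights(network: Network, scale: int = 10,
                           normalize: bool = False) -> Network:
    """Attach integer partitioning weights ``iweight`` to every edge.

    iweight = round-half-up(scale * weight), or, with ``normalize``,
    round-half-up(scale * weight / mean weight) so a typical edge carries
    ``scale`` regardless of the layer's absolute weight scale (needed for the
    combined network, whose normalised weights are ~1/|E|). Unweighted
    networks get iweight = 1. Edges with iweight 0 remain in the network but
    are ignored by the partitioning view.
    """
    if not network.weighted:
        for _, _, d in network.graph.edges(data=True):
            d["iweight"] = 1
        return network
    denom = network.mean_edge_weight() if normalize else 1.0
    for _, _, d in network.graph.edges(data=True):
        d["iweight"] = int(math.floor(scale * d["weight"] / denom + 0.5))
    return network


def write_graphml(network: Network, path) -> Path:
    """Export for external graph viewers."""
    path = Path(path)
    g = nx.Graph()
    for node in sorted(network.graph.nodes, key=str):
        g.add_node(node, **network.graph.nodes[node])
    edges = sorted((tuple(sorted((u, v), key=str)) for u, v in network.graph.edges()))
    for u, v in edges:
        data = dict(network.graph[u][v])
        if "layers" in data:
            data["layers"] = ",".join(data["layers"])
        g.add_edge(u, v, **data)
    nx.write_graphml(g, path)
    return path
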