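"""Synthetic multilayer benchmark generator.

Emulates the statistical structure the analysis assumes: several interaction
layers over a shared gene universe containing planted, partially shared
modules (a planted-partition model: intra-module pairs connect with p_in,
all other pairs with p_out); a treatment-call matrix whose co-regulation
structure mirrors the modules; and a three-namespace ontology whose leaf
terms align (with annotation dropout noise) to the planted modules.

One structural feature drives the combined-network analyses: an optional
*bridge module* whose within-module edges are striped across the two
unweighted layers as perfect matchings (together forming a cycle). Each
single layer then sees only components of two nodes — below the subgraph
size floor — while the combined network sees a connected module, so the
bridge's aligned terms can only be discovered by integrating layers.
Bridge-gene pairs are excluded from background edges and background calls so
the stripes stay matchings.

The default design ("bench-A") is the study condition for all acceptance
properties: 500 genes, 8 modules of 12, layers ppi/genetic/co-regulation,
modules 0-5 shared between ppi and genetic and co-regulated, module 6
ppi-private, module 7 genetic-private, p_in=0.6, p_out=0.02,
annotation noise 0.1, artefact seeds 11 (layers), 13 (calls), 17 (ontology).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from modulenet.coreg import TreatmentCalls
from modulenet.enrichment import AnnotationMap, Ontology, NAMESPACES
from modulenet.netio import Network, write_edge_list


@dataclass
class PlantedDesign:
    """Parameters of one synthetic benchmark instance."""

    n_genes: int = 500
    n_modules: int = 8
    module_size: int = 12
    p_in: float = 0.6
    p_out: float = 0.02
    shared_modules: tuple = (0, 1, 2, 3, 4, 5)
    layer_private: dict = field(default_factory=lambda: {"ppi": (6,), "genetic": (7,)})
    coreg_modules: tuple = (0, 1, 2, 3, 4, 5)
    bridge: bool = True
    annotation_noise: float = 0.1
    # treatment-call parameters
    n_treatments: int = 60
    p_active_module: float = 0.3
    p_call: float = 0.9
    p_background: float = 0.02
    # ontology parameters
    background_term_sizes: tuple = (
        # unaligned specialist background terms; five genes make spurious
        # enrichment doubly unlikely: partial overlaps stay above the BH
        # threshold of a grid-sized family, and complete capture of all five
        # genes by one spurious subgraph is vanishingly rare
        (5,) * 2000
    )
    markers_per_module: int = 3
    marker_size: int = 4
    p_iea: float = 0.3
    # per-artefact seeds
    layer_seed: int = 11
    calls_seed: int = 13
    ontology_seed: int = 17

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        used = self.n_modules * self.module_size + (12 if self.bridge else 0)
        if used > self.n_genes:
            raise ValueError("modules (plus bridge) exceed the gene universe")

    # -- gene bookkeeping ------------------------------------------------
    def gene(self, i: int) -> str:
        return f"G{i:04d}"

    def genes(self) -> list:
        return [self.gene(i) for i in range(self.n_genes)]

    def module_genes(self, m: int) -> list:
        lo = m * self.module_size
        return [self.gene(i) for i in range(lo, lo + self.module_size)]

    def bridge_genes(self) -> list:
        if not self.bridge:
            return []
        lo = self.n_modules * self.module_size
        return [self.gene(i) for i in range(lo, lo + 12)]

    def module_of(self) -> np.ndarray:
        """Per-gene module index; -1 background, n_modules marks the bridge."""
        mod = np.full(self.n_genes, -1, dtype=np.int64)
        for m in range(self.n_modules):
            mod[m * self.module_size:(m + 1) * self.module_size] = m
        if self.bridge:
            lo = self.n_modules * self.module_size
            mod[lo:lo + 12] = self.n_modules
        return mod

    def layer_modules(self, layer: str) -> tuple:
        return tuple(sorted(set(self.shared_modules) | set(self.layer_private.get(layer, ()))))


def bench_a(**overrides) -> PlantedDesign:
    """The default benchmark design (see module docstring)."""
    return PlantedDesign(**overrides)


def _bridge_stripe(genes: list, layer_index: int) -> list:
    """Perfect matching: even cycle edges for layer 0, odd ones for layer 1."""
    n = len(genes)
    return [(genes[i], genes[(i + 1) % n]) for i in range(layer_index, n, 2)]


def generate_layers(design: PlantedDesign):
    """The two unweighted layers plus ground truth.

    Returns (networks, truth) where networks is a list of Network in the
    order of design.layer_private keys and truth maps module names to gene
    lists with per-layer expression records.
    """
    rng = np.random.default_rng(design.layer_seed)
    n = design.n_genes
    mod = design.module_of()
    iu, ju = np.triu_indices(n, k=1)
    mi, mj = mod[iu], mod[ju]
    same_module = (mi == mj) & (mi >= 0) & (mi < design.n_modules)
    bridge_pair = (mi == design.n_modules) & (mj == design.n_modules)

    layers = []
    layer_names = list(design.layer_private)
    genes = design.genes()
    for li, layer in enumerate(layer_names):
        expressed = design.layer_modules(layer)
        thr = np.full(iu.shape, design.p_out)
        expressed_pair = same_module & np.isin(mi, expressed)
        thr[expressed_pair] = design.p_in
        thr[same_module & ~np.isin(mi, expressed)] = design.p_out
        thr[bridge_pair] = 0.0
        draws = rng.random(iu.shape)
        sel = draws < thr
        edges = [(genes[a], genes[b]) for a, b in zip(iu[sel], ju[sel])]
        if design.bridge:
            edges.extend(_bridge_stripe(design.bridge_genes(), li % 2))
        net = Network.from_edges(layer, edges, weighted=False, nodes=genes)
        layers.append(net)

    truth = {
        "modules": {f"M{m}": design.module_genes(m) for m in range(design.n_modules)},
        "shared_modules": [f"M{m}" for m in design.shared_modules],
        "layer_modules": {layer: [f"M{m}" for m in design.layer_modules(layer)]
                          for layer in layer_names},
        "coreg_modules": [f"M{m}" for m in design.coreg_modules],
        "bridge_genes": design.bridge_genes(),
    }
    return layers, truth


def generate_treatment_calls(design: PlantedDesign,
                             n_treatments: int | None = None,
                             p_active_module: float | None = None,
                             p_background: float | None = None) -> TreatmentCalls:
    """Simulate the gene x treatment significance-call matrix.

    Per treatment each co-regulated module is active with p_active_module;
    genes of active modules are called with p_call, all other responsive
    genes with p_background. Bridge genes never respond (their module is
    structural, split across the physical layers).
    """
    t = design.n_treatments if n_treatments is None else n_treatments
    p_act = design.p_active_module if p_active_module is None else p_active_module
    p_bg = design.p_background if p_background is None else p_background
    if not (0 <= p_act <= 1 and 0 <= p_bg <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if t < 1:
        raise ValueError("need at least one treatment")
    rng = np.random.default_rng(design.calls_seed)
    mod = design.module_of()
    active = rng.random((len(design.coreg_modules), t)) < p_act
    prob = np.full((design.n_genes, t), p_bg)
    for row, m in enumerate(sorted(design.coreg_modules)):
        sel = mod == m
        prob[np.ix_(sel, active[row])] = design.p_call
    if design.bridge:
        prob[mod == design.n_modules, :] = 0.0
    calls = (rng.random((design.n_genes, t)) < prob).astype(np.uint8)
    treatments = [f"T{j:03d}" for j in range(t)]
    return TreatmentCalls(design.genes(), treatments, calls)


def generate_ontology(design: PlantedDesign):
    """A three-namespace ontology aligned (with dropout noise) to the modules.

    Per namespace: one root; two mid-level terms; one leaf term per module
    plus one for the bridge module (linked by part_of for variety); a few
    small *marker* terms per module (specific functions, children of the
    module's leaf, annotating a random subset of its genes); and a block of
    unaligned background terms of the requested sizes. Direct annotations
    carry evidence codes (IEA with probability p_iea, else an experimental
    code).

    Returns (ontology, direct_annotations, records) where records is the
    (gene, term, evidence) list the GAF-like file is written from.
    """
    rng = np.random.default_rng(design.ontology_seed)
    namespaces: dict = {}
    parents: dict = {}
    records: list = []
    counter = [0]

    def new_term(ns: str) -> str:
        counter[0] += 1
        term = f"GO:{8000000 + counter[0]:07d}"
        namespaces[term] = ns
        parents[term] = set()
        return term

    def annotate(term: str, gene_list):
        for g in gene_list:
            ev = "IEA" if rng.random() < design.p_iea else \
                ["IDA", "IMP", "IGI"][int(rng.integers(3))]
            records.append((g, term, ev))

    def noisy(gene_list):
        return [g for g in gene_list if rng.random() >= design.annotation_noise]

    def add_markers(leaf: str, ns: str, role: str, gene_list):
        for _ in range(design.markers_per_module):
            t = new_term(ns)
            parents[t].add(leaf)
            term_roles[t] = f"marker:{role}"
            pick = rng.choice(len(gene_list), size=min(design.marker_size,
                                                       len(gene_list)),
                              replace=False)
            annotate(t, noisy([gene_list[int(i)] for i in sorted(pick)]))

    genes = design.genes()
    term_roles: dict = {}
    for ns in NAMESPACES:
        root = new_term(ns)
        term_roles[root] = "root"
        mids = [new_term(ns), new_term(ns)]
        for mid in mids:
            parents[mid].add(root)
            term_roles[mid] = "mid"
        for m in range(design.n_modules):
            leaf = new_term(ns)
            parents[leaf].add(mids[0] if m < design.n_modules // 2 else mids[1])
            term_roles[leaf] = f"module:M{m}"
            annotate(leaf, noisy(design.module_genes(m)))
            add_markers(leaf, ns, f"M{m}", design.module_genes(m))
        if design.bridge:
            bridge_leaf = new_term(ns)
            parents[bridge_leaf].add(mids[1])  # written as part_of
            term_roles[bridge_leaf] = "bridge"
            annotate(bridge_leaf, noisy(design.bridge_genes()))
            # no marker children: the bridge's term signal is its leaf;4-gene
            # subsets of a cycle module are rarely captured whole
        for size in design.background_term_sizes:
            t = new_term(ns)
            parents[t].add(root)
            term_roles[t] = "random"
            members = rng.choice(len(genes), size=size, replace=False)
            annotate(t, [genes[int(i)] for i in sorted(members)])

    ontology = Ontology(namespaces, parents)
    ontology.term_roles = term_roles
    gene_terms: dict = {}
    for g, t, _ in records:
        gene_terms.setdefault(g, set()).add(t)
    direct = AnnotationMap({g: frozenset(ts) for g, ts in gene_terms.items()})
    return ontology, direct, records


def write_obo(ontology: Ontology, path, part_of_roles=("bridge",)) -> Path:
    """Serialise the ontology as a minimal OBO file.

    Terms whose role is listed in ``part_of_roles`` link to their parent via
    a part_of relationship; everything else uses is_a.
    """
    path = Path(path)
    roles = getattr(ontology, "term_roles", {})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(ontology.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            fh.write(f"namespace: {ontology.namespaces[term]}\n")
            for parent in sorted(ontology.parents[term]):
                if roles.get(term) in part_of_roles:
                    fh.write(f"relationship: part_of {parent}\n")
                else:
                    fh.write(f"is_a: {parent}\n")
    return path


def write_annotations(records: list, path) -> Path:
    """GAF-like TSV: gene, term, evidence code."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gene\tterm\tevidence\n")
        for gene, term, ev in sorted(records):
            fh.write(f"{gene}\t{term}\t{ev}\n")
    return path


def write_bench(design: PlantedDesign, outdir) -> dict:
    """Materialise a benchmark instance as plain-text files.

    Emits the unweighted layers in the edge-list dialect, the treatment-call
    TSV, the OBO + annotation files and a ground-truth JSON sufficient to
    score module recovery. Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layers, truth = generate_layers(design)
    calls = generate_treatment_calls(design)
    ontology, _, records = generate_ontology(design)
    paths = {}
    for net in layers:
        p = outdir / f"{net.layer_name}.edges.txt"
        write_edge_list(net, p)
        paths[net.layer_name] = str(p)
    calls_path = outdir / "treatment_calls.tsv"
    calls.write_tsv(calls_path)
    paths["calls"] = str(calls_path)
    paths["obo"] = str(write_obo(ontology, outdir / "ontology.obo"))
    paths["annotations"] = str(write_annotations(records, outdir / "annotations.tsv"))
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump({"design": asdict(design), "truth": truth}, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = str(truth_path)
    return paths
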