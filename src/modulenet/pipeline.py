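"""End-to-end orchestration: inputs -> networks -> multi-resolution
partitioning -> validated subgraphs -> cross-network congruence -> enrichment
and coverage reports.

Every stage is a plain function over in-memory objects; ``run_all`` chains
them and (optionally) writes a reproducible report bundle whose numeric
tables regenerate byte-identically from the same config and seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from modulenet import congruence as cg
from modulenet import enrichment as enr
from modulenet import synthdata
from modulenet.coreg import TreatmentCalls, build_coregulation_network
from modulenet.netio import (
    Network,
    assign_integer_weights,
    combine_networks,
    common_gene_networks,
    read_edge_list,
    write_edge_list,
    write_graphml,
)
from modulenet.partition import partition_graph, plan_k_values
from modulenet.subgraphs import (
    DistanceCache,
    Subgraph,
    dedupe_subgraphs,
    edge_density,
    extract_subgraphs,
    validation_pvalues,
    weighted_density,
)

log = logging.getLogger("modulenet")


@dataclass
class RunConfig:
    """All thresholds, seeds and input choices of one analysis run."""

    design: synthdata.PlantedDesign | None = None
    input_paths: dict | None = None
    outdir: str | None = None
    min_size: int = 3
    balance_tol: float = 1.10
    alpha_validate: float = 0.05
    n_min: int = 3
    m_min: float = 0.2
    fdr_alpha: float = 0.05
    mcc_bin_threshold: float = 0.2
    high_degree_percentile: float = 97.5
    coreg_scale: int = 10
    combined_scale: int = 10
    universe_mode: str = "network_union"
    annotation_modes: tuple = ("all", "no_iea", "only_iea")
    common_gene: bool = False
    export_subgraph_edges: bool = False
    partition_seed: int = 101
    randomization_seed: int = 202

    def __post_init__(self):
        checks = [
            0 < self.alpha_validate < 1, 0 < self.fdr_alpha < 1,
            self.n_min >= 1, -1 <= self.m_min <= 1,
            0 <= self.high_degree_percentile <= 100,
            self.coreg_scale >= 1, self.balance_tol >= 1.0,
            self.min_size >= 2,
        ]
        if not all(checks):
            raise ValueError("a RunConfig threshold is out of range")
        if self.design is None and self.input_paths is None:
            self.design = synthdata.bench_a()
        if isinstance(self.design, dict):
            self.design = synthdata.PlantedDesign(**self.design)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = asdict(self)
        if self.design is not None:
            out["design"] = asdict(self.design)
        # run-location fields would make otherwise identical bundles differ
        out.pop("outdir", None)
        return out


@dataclass
class RunResult:
    """Everything a downstream consumer or report writer needs."""

    config: RunConfig
    truth: dict | None
    networks: dict
    registries: dict               # network -> {subgraph id -> Subgraph}
    catalogues: dict               # network -> DataFrame
    hits: list
    best_graph: nx.Graph
    high_degree_ids: list
    neighbourhood_ids: set
    reciprocal_hits: list
    merged: list
    hit_summary: pd.DataFrame
    enrichments: dict              # network -> DataFrame (mode 'all')
    merged_enrichment: pd.DataFrame
    coverages: dict                # mode -> network -> CoverageReport
    randomized_coverage: dict      # network -> CoverageReport
    coenrichment: dict
    novel_pairs: list
    relative_enrichment: dict      # network -> DataFrame
    hd_test: dict
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def load_inputs(config: RunConfig):
    """Generate (synthetic design) or load (file paths) the raw inputs."""
    if config.input_paths is not None:
        paths = config.input_paths
        layers = [read_edge_list(paths[name], weighted=False, layer_name=name)
                  for name in sorted(paths) if name.startswith("layer:")]
        layers = [Network(n.layer_name.split(":", 1)[1], n.graph, n.weighted)
                  for n in layers]
        calls = TreatmentCalls.read_tsv(paths["calls"]) if "calls" in paths else None
        ontology, _ = enr.load_ontology_and_annotations(paths["obo"], paths["annotations"])
        annotations = {
            mode: enr.read_annotations(paths["annotations"], mode=mode).propagated(ontology)
            for mode in config.annotation_modes
        }
        truth = None
        if "ground_truth" in paths:
            with open(paths["ground_truth"], "r", encoding="utf-8") as fh:
                truth = json.load(fh)["truth"]
        return layers, calls, ontology, annotations, truth
    design = config.design
    layers, truth = synthdata.generate_layers(design)
    calls = synthdata.generate_treatment_calls(design)
    ontology, direct, records = synthdata.generate_ontology(design)
    annotations = {}
    for mode in config.annotation_modes:
        kept: dict = {}
        for gene, term, ev in records:
            if mode == "no_iea" and ev == "IEA":
                continue
            if mode == "only_iea" and ev != "IEA":
                continue
            kept.setdefault(gene, set()).add(term)
        amap = enr.AnnotationMap({g: frozenset(t) for g, t in kept.items()})
        annotations[mode] = amap.propagated(ontology)
    return layers, calls, ontology, annotations, truth


def build_networks(config: RunConfig, layers: list, calls) -> dict:
    """Assemble the per-layer, combined and (optionally) common-gene
    networks, with integer partitioning weights attached."""
    networks = {}
    for layer in layers:
        assign_integer_weights(layer)
        networks[layer.layer_name] = layer
    if calls is not None:
        coreg_net = build_coregulation_network(calls, scale=config.coreg_scale)
        networks[coreg_net.layer_name] = coreg_net
    members = [networks[name] for name in sorted(networks)]
    if len(members) >= 2:
        combined = combine_networks(members, name="combined")
        assign_integer_weights(combined, scale=config.combined_scale, normalize=True)
        networks["combined"] = combined
    if config.common_gene:
        singles = [networks[n] for n in sorted(networks) if n != "combined"]
        for net in common_gene_networks(singles):
            if not net.weighted:
                assign_integer_weights(net)
            networks[f"{net.layer_name}_common"] = net
        if len(singles) >= 2:
            cg_combined = combine_networks(
                common_gene_networks(singles), name="combined_common")
            assign_integer_weights(cg_combined, scale=config.combined_scale, normalize=True)
            networks["combined_common"] = cg_combined
    return networks


def discover_subgraphs(config: RunConfig, network: Network):
    """Multi-resolution partitioning, extraction, validation, dedup."""
    t0 = time.monotonic()
    plan = plan_k_values(network.n_nodes(), config.min_size)
    cache = DistanceCache(network)
    mean_w = network.mean_edge_weight() if network.n_edges() else 1.0
    retained: list[Subgraph] = []
    for k in plan.ks:
        part = partition_graph(network, k, seed=config.partition_seed + k,
                               balance_tol=config.balance_tol)
        cohort = extract_subgraphs(network, part, min_nodes=config.min_size)
        pvals = validation_pvalues(cohort, cache)
        for sub, p in zip(cohort, pvals):
            sub.validation_p = p
            if p is None or p < config.alpha_validate:
                retained.append(sub)
    subs = dedupe_subgraphs(retained)
    registry = {s.id: s for s in subs}
    rows = []
    for s in sorted(subs, key=lambda s: s.id):
        rows.append({
            "id": s.id,
            "layer": s.source_layer,
            "k_origin": ",".join(str(k) for k in s.k_origin),
            "size": s.size(),
            "edges": s.n_edges(),
            "density": edge_density(s),
            "weighted_density": weighted_density(s, mean_w) if network.weighted else np.nan,
            "validation_p": np.nan if s.validation_p is None else s.validation_p,
            "genes": ";".join(sorted(s.genes, key=str)),
        })
    catalogue = pd.DataFrame(rows, columns=[
        "id", "layer", "k_origin", "size", "edges", "density",
        "weighted_density", "validation_p", "genes"])
    log.info("subgraphs[%s]: %d k-values, %d retained, %.1fs",
             network.layer_name, len(plan.ks), len(subs), time.monotonic() - t0)
    return registry, catalogue


def registry_from_catalogue(catalogue: pd.DataFrame, network: Network) -> dict:
    """Rebuild Subgraph objects from a catalogue TSV (file-based reruns)."""
    registry = {}
    for _, row in catalogue.iterrows():
        genes = frozenset(row["genes"].split(";"))
        vp = row["validation_p"]
        registry[row["id"]] = Subgraph(
            id=row["id"], source_layer=row["layer"], genes=genes,
            graph=network.graph.subgraph(genes).copy(),
            k_origin=tuple(int(k) for k in str(row["k_origin"]).split(",")),
            validation_p=None if pd.isna(vp) else float(vp),
        )
    return registry


def run_congruence(config: RunConfig, networks: dict, registries: dict):
    """All-pairs congruence between the single-data-type networks."""
    single = [n for n in sorted(registries) if n != "combined"
              and not n.endswith("_common")]
    hits = []
    for i, a in enumerate(single):
        for b in single[i + 1:]:
            universe = networks[a].nodes | networks[b].nodes
            hits.extend(cg.score_layer_pair(
                list(registries[a].values()), list(registries[b].values()),
                universe, n_min=config.n_min, m_min=config.m_min,
                mode=config.universe_mode))
    hits = cg.call_best_hits(hits, fdr_alpha=config.fdr_alpha)
    graph = cg.build_best_hit_graph(hits)
    hd = cg.high_degree(graph, config.high_degree_percentile)
    members = cg.high_degree_neighbourhoods(graph, hd)
    rbh = cg.reciprocal_best_hits(hits)
    rows = []
    for i, a in enumerate(single):
        for b in single[i + 1:]:
            pair_hits = [h for h in hits if {h.layer_a, h.layer_b} == {a, b}]
            rows.append({
                "network_a": a, "network_b": b,
                "tested_pairs": len(pair_hits),
                "significant": sum(h.q < config.fdr_alpha for h in pair_hits),
                "best_hits_a_to_b": sum(h.best_a_to_b for h in pair_hits),
                "best_hits_b_to_a": sum(h.best_b_to_a for h in pair_hits),
                "reciprocal_best_hits": sum(h.is_reciprocal() for h in pair_hits),
            })
    summary = pd.DataFrame(rows)
    return hits, graph, hd, members, rbh, summary


def merge_reciprocal(config: RunConfig, rbh: list, registries: dict,
                     networks: dict) -> list:
    singles = [networks[n] for n in sorted(networks)
               if n != "combined" and not n.endswith("_common")]
    merged = []
    flat = {}
    for reg in registries.values():
        flat.update(reg)
    for hit in sorted(rbh, key=lambda h: (h.subgraph_a, h.subgraph_b)):
        merged.append(cg.merge_subgraphs(flat[hit.subgraph_a], flat[hit.subgraph_b],
                                         singles, hit))
    return merged


def run_enrichment(config: RunConfig, networks: dict, registries: dict,
                   merged: list, ontology, annotations: dict):
    """Per-network enrichment for every annotation mode, coverage reports,
    the randomisation control and the merged-subnetwork enrichment."""
    enrichments: dict = {}
    coverages: dict = {mode: {} for mode in config.annotation_modes}
    for name in sorted(registries):
        genes = networks[name].nodes
        subs = {sid: s.genes for sid, s in registries[name].items()}
        for mode in config.annotation_modes:
            df = enr.enrich_catalogue(subs, annotations[mode], genes,
                                      fdr_alpha=config.fdr_alpha)
            coverages[mode][name] = enr.coverage(df, annotations[mode], ontology, genes)
            if mode == "all":
                enrichments[name] = df
    randomized: dict = {}
    # annotated genes may extend past the networks (isolated genes are not
    # representable in edge-list files); permute over the union of both
    pool = set().union(*(networks[n].nodes for n in sorted(networks)))
    pool |= set(annotations["all"].gene_terms)
    rand_ann = enr.randomize_annotations(annotations["all"],
                                         seed=config.randomization_seed,
                                         universe=pool)
    for name in sorted(registries):
        genes = networks[name].nodes
        subs = {sid: s.genes for sid, s in registries[name].items()}
        df = enr.enrich_catalogue(subs, rand_ann, genes, fdr_alpha=config.fdr_alpha)
        randomized[name] = enr.coverage(df, rand_ann, ontology, genes)
    merged_df = pd.DataFrame(columns=["subgraph", "term", "tp", "fp", "fn",
                                      "tn", "p", "q", "mcc", "enriched"])
    if merged and "combined" in networks:
        merged_sets = {m.id: m.genes for m in merged}
        merged_df = enr.enrich_catalogue(merged_sets, annotations["all"],
                                         networks["combined"].nodes,
                                         fdr_alpha=config.fdr_alpha)
    return enrichments, coverages, randomized, merged_df


def high_degree_enrichment_test(enrichments: dict, registries: dict,
                                neighbourhood_ids: set) -> dict:
    """One-sided Mann-Whitney U: are subgraphs inside high-degree
    neighbourhoods enriched for more terms than those outside?"""
    counts = {}
    for name, df in enrichments.items():
        if name == "combined" or name.endswith("_common"):
            continue
        per_sub = (df[df["enriched"]].groupby("subgraph").size()
                   if len(df) else pd.Series(dtype=int))
        for sid in registries[name]:
            counts[sid] = int(per_sub.get(sid, 0))
    inside = [c for sid, c in sorted(counts.items()) if sid in neighbourhood_ids]
    outside = [c for sid, c in sorted(counts.items()) if sid not in neighbourhood_ids]
    out = {"n_inside": len(inside), "n_outside": len(outside),
           "mean_inside": float(np.mean(inside)) if inside else 0.0,
           "mean_outside": float(np.mean(outside)) if outside else 0.0,
           "p_value": 1.0}
    if inside and outside:
        stat = mannwhitneyu(inside, outside, alternative="greater")
        out["p_value"] = float(stat.pvalue)
    return out


def gene_recurrence(registries: dict) -> dict:
    """Diagnostic: the largest fraction of one network's subgraphs sharing a
    single gene (mirrors the 'a gene appears in at most ~1% of subgraphs'
    sanity check)."""
    out = {}
    for name in sorted(registries):
        subs = registries[name]
        if not subs:
            out[name] = 0.0
            continue
        freq: dict = {}
        for s in subs.values():
            for g in s.genes:
                freq[g] = freq.get(g, 0) + 1
        out[name] = max(freq.values()) / len(subs)
    return out


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis; write the report bundle when an output
    directory is configured."""
    t0 = time.monotonic()
    stage = "inputs"
    try:
        layers, calls, ontology, annotations, truth = load_inputs(config)
        stage = "networks"
        networks = build_networks(config, layers, calls)
        stage = "subgraphs"
        registries, catalogues = {}, {}
        for name in sorted(networks):
            registries[name], catalogues[name] = discover_subgraphs(config, networks[name])
        stage = "congruence"
        hits, graph, hd, members, rbh, summary = run_congruence(config, networks, registries)
        stage = "merge"
        merged = merge_reciprocal(config, rbh, registries, networks)
        stage = "enrichment"
        enrichments, coverages, randomized, merged_df = run_enrichment(
            config, networks, registries, merged, ontology, annotations)
        stage = "reports"
        tables, novel = enr.coenrichment_pairs(
            {n: df for n, df in enrichments.items()
             if n != "combined" and not n.endswith("_common")},
            ontology, merged_enrichments=merged_df)
        relenr = {}
        for name in sorted(enrichments):
            try:
                relenr[name] = enr.relative_enrichment_by_term_size(
                    enrichments[name], annotations["all"], networks[name].nodes,
                    mcc_threshold=config.mcc_bin_threshold)
            except ValueError:
                relenr[name] = None
        hd_test = high_degree_enrichment_test(enrichments, registries, members)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "config": config.to_jsonable(),
        "n_networks": len(networks),
        "subgraph_counts": {n: len(r) for n, r in sorted(registries.items())},
        "congruence_tests": len(hits),
        "reciprocal_best_hits": len(rbh),
        "high_degree_subgraphs": len(hd),
        "gene_recurrence_max_fraction": gene_recurrence(registries),
        "coreg_present": calls is not None,
    }
    result = RunResult(
        config=config, truth=truth, networks=networks, registries=registries,
        catalogues=catalogues, hits=hits, best_graph=graph,
        high_degree_ids=hd, neighbourhood_ids=members, reciprocal_hits=rbh,
        merged=merged, hit_summary=summary, enrichments=enrichments,
        merged_enrichment=merged_df, coverages=coverages,
        randomized_coverage=randomized, coenrichment=tables,
        novel_pairs=novel, relative_enrichment=relenr, hd_test=hd_test,
        provenance=provenance,
    )
    if config.outdir is not None:
        write_bundle(Path(config.outdir), result)
    log.info("run_all finished in %.1fs", time.monotonic() - t0)
    return result


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def _hits_frame(hits) -> pd.DataFrame:
    rows = []
    for h in sorted(hits, key=lambda h: (h.subgraph_a, h.subgraph_b)):
        rows.append({
            "subgraph_a": h.subgraph_a, "subgraph_b": h.subgraph_b,
            "layer_a": h.layer_a, "layer_b": h.layer_b,
            "size_a": h.size_a, "size_b": h.size_b,
            "tp": h.counts.tp, "fp": h.counts.fp, "fn": h.counts.fn,
            "tn": h.counts.tn, "mcc": h.mcc, "p": h.p, "q": h.q,
            "best_a_to_b": h.best_a_to_b, "best_b_to_a": h.best_b_to_a,
            "reciprocal": h.is_reciprocal(),
        })
    return pd.DataFrame(rows, columns=[
        "subgraph_a", "subgraph_b", "layer_a", "layer_b", "size_a", "size_b",
        "tp", "fp", "fn", "tn", "mcc", "p", "q",
        "best_a_to_b", "best_b_to_a", "reciprocal"])


def coverage_frame(coverages: dict) -> pd.DataFrame:
    """Coverage reports (network x namespace rows) as one flat table."""
    rows = []
    for name in sorted(coverages):
        frame = coverages[name].as_frame()
        frame.insert(0, "network", name)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def write_bundle(outdir: Path, result: RunResult) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str):
        df.to_csv(outdir / name, sep="\t", index=False)

    for name in sorted(result.catalogues):
        tsv(result.catalogues[name], f"subgraphs_{name}.tsv")
        if result.config.export_subgraph_edges:
            edge_dir = outdir / f"subgraph_edges_{name}"
            edge_dir.mkdir(exist_ok=True)
            for sid, sub in sorted(result.registries[name].items()):
                fname = sid.replace(":", "_") + ".txt"
                write_edge_list(Network(name, sub.graph, result.networks[name].weighted),
                                edge_dir / fname)
    tsv(_hits_frame(result.hits), "congruence_hits.tsv")
    tsv(result.hit_summary, "best_hit_summary.tsv")
    write_graphml(Network("best_hits", result.best_graph), outdir / "best_hit_graph.graphml")
    with open(outdir / "high_degree.json", "w", encoding="utf-8") as fh:
        json.dump({"high_degree": sorted(result.high_degree_ids),
                   "neighbourhood_members": sorted(result.neighbourhood_ids),
                   "enrichment_test": result.hd_test}, fh, indent=1, sort_keys=True)
    merged_rows = []
    for m in result.merged:
        top = max(m.node_betweenness.items(), key=lambda kv: (kv[1], kv[0]),
                  default=("", 0.0))
        merged_rows.append({
            "id": m.id, "subgraph_a": m.subgraph_a, "subgraph_b": m.subgraph_b,
            "n_genes": len(m.genes), "n_edges": m.graph.number_of_edges(),
            "top_betweenness_gene": top[0], "top_betweenness": top[1],
            "genes": ";".join(sorted(m.genes, key=str)),
        })
    tsv(pd.DataFrame(merged_rows, columns=[
        "id", "subgraph_a", "subgraph_b", "n_genes", "n_edges",
        "top_betweenness_gene", "top_betweenness", "genes"]),
        "merged_reciprocal_subnetworks.tsv")
    edge_rows = []
    for m in result.merged:
        for u, v, d in sorted(m.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            a, b = sorted((u, v), key=str)
            edge_rows.append({"merged_id": m.id, "u": a, "v": b,
                              "layers": ",".join(d["layers"]),
                              "edge_betweenness": m.edge_betweenness[(a, b)]})
    tsv(pd.DataFrame(edge_rows, columns=["merged_id", "u", "v", "layers",
                                         "edge_betweenness"]),
        "merged_reciprocal_edges.tsv")
    for name in sorted(result.enrichments):
        tsv(result.enrichments[name], f"enrichment_{name}.tsv")
    tsv(result.merged_enrichment, "enrichment_merged_reciprocal.tsv")
    for mode in result.coverages:
        tsv(coverage_frame(result.coverages[mode]), f"coverage_{mode}.tsv")
    tsv(coverage_frame(result.randomized_coverage), "coverage_randomized.tsv")
    for name in sorted(result.coenrichment):
        tsv(result.coenrichment[name], f"coenrichment_{name}.tsv")
    with open(outdir / "novel_coenriched_pairs.json", "w", encoding="utf-8") as fh:
        json.dump([list(p) for p in result.novel_pairs], fh, indent=1)
    for name in sorted(result.relative_enrichment):
        df = result.relative_enrichment[name]
        if df is not None:
            tsv(df, f"relative_enrichment_{name}.tsv")
    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(result.provenance, fh, indent=1, sort_keys=True)
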