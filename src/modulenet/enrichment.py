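"""Gene Ontology enrichment, coverage and co-enrichment statistics.

Subgraphs are assigned function by upper-tail hypergeometric (Fisher) tests:
the population is the source network's gene set, population successes are the
network genes annotated with a term (after true-path propagation across is_a
and part_of), and the sample is the subgraph. P-values are pooled across all
(subgraph, term) tests of a run for Benjamini-Hochberg correction, and each
result carries an MCC measuring how exactly the subgraph captures the term.
*Coverage* of an ontology namespace is the percentage of eligible terms
(those with at least two annotated genes in the network) enriched in at least
one subgraph. *Co-enrichment* pairs are two terms over-represented in the
same subgraph, classified by namespace and ancestor relations. A
label-permutation randomisation of the annotations provides the negative
control, and relative enrichment by term-size bin profiles the generality of
the captured functions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.sparse import csr_matrix

from modulenet import stats

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class Ontology:
    """A term DAG with namespaces; parent links are is_a and part_of."""

    def __init__(self, namespaces: dict, parents: dict):
        for term, ns in namespaces.items():
            if ns not in NAMESPACES:
                raise ValueError(f"term {term} has unknown namespace {ns!r}")
        self.namespaces = dict(namespaces)
        self.parents = {t: frozenset(parents.get(t, ())) for t in namespaces}
        dag = nx.DiGraph()
        dag.add_nodes_from(self.namespaces)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.namespaces:
                    raise ValueError(f"parent {p} of {child} is not a term")
                dag.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("ontology parent graph is cyclic")
        self._dag = dag
        self._anc: dict = {}

    @property
    def terms(self) -> set:
        return set(self.namespaces)

    def ancestors(self, term: str) -> frozenset:
        """All (proper) ancestors reachable through is_a/part_of."""
        cached = self._anc.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._dag, term))
            self._anc[term] = cached
        return cached

    def related(self, t1: str, t2: str) -> bool:
        """True when one term is an ancestor or descendant of the other."""
        return t1 in self.ancestors(t2) or t2 in self.ancestors(t1)

    @classmethod
    def from_obo(cls, path) -> "Ontology":
        g = obonet.read_obo(path)
        namespaces, parents = {}, {}
        for term, data in g.nodes(data=True):
            ns = data.get("namespace")
            if ns is None:
                raise ValueError(f"term {term} lacks a namespace")
            namespaces[term] = ns
            ps = set(data.get("is_a", ()))
            for rel in data.get("relationship", ()):
                kind, target = rel.split(" ", 1)
                if kind == "part_of":
                    ps.add(target.strip())
            parents[term] = ps
        return cls(namespaces, parents)


@dataclass
class AnnotationMap:
    """gene -> set of term ids; build with :meth:`propagated` before use so
    the true-path rule (a gene annotated to a term carries all ancestors)
    holds."""

    gene_terms: dict

    def genes(self) -> set:
        return set(self.gene_terms)

    def propagated(self, ontology: Ontology) -> "AnnotationMap":
        out = {}
        for gene, terms in self.gene_terms.items():
            full = set()
            for t in terms:
                full.add(t)
                full |= ontology.ancestors(t)
            out[gene] = frozenset(full)
        return AnnotationMap(out)

    def restricted(self, genes: set) -> "AnnotationMap":
        return AnnotationMap({g: t for g, t in self.gene_terms.items() if g in genes})

    def term_genes(self) -> dict:
        """Invert to term -> frozenset of genes."""
        inv: dict = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                inv.setdefault(t, set()).add(gene)
        return {t: frozenset(g) for t, g in inv.items()}


def read_annotations(path, mode: str = "all") -> AnnotationMap:
    """Read a GAF-like TSV (gene, term, evidence code), filtered by
    annotation mode: 'all', 'no_iea' (drop IEA evidence) or 'only_iea'."""
    if mode not in ("all", "no_iea", "only_iea"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    gene_terms: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"annotation row needs gene, term, evidence: {line!r}")
            gene, term, evidence = fields[0], fields[1], fields[2]
            if mode == "no_iea" and evidence == "IEA":
                continue
            if mode == "only_iea" and evidence != "IEA":
                continue
            gene_terms.setdefault(gene, set()).add(term)
    return AnnotationMap({g: frozenset(t) for g, t in gene_terms.items()})


def load_ontology_and_annotations(obo_path, gaf_path, mode: str = "all"):
    """Parse ontology and annotations, filter by evidence mode, propagate."""
    ontology = Ontology.from_obo(obo_path)
    raw = read_annotations(gaf_path, mode=mode)
    return ontology, raw.propagated(ontology)


def eligible_terms(annotations: AnnotationMap, network_genes: set,
                   min_genes: int = 2) -> dict:
    """term -> annotated network genes, for terms with >= min_genes of them.

    Terms with one or no associated genes in the network are excluded from
    both testing and coverage denominators.
    """
    restricted = annotations.restricted(network_genes)
    return {t: g for t, g in restricted.term_genes().items() if len(g) >= min_genes}


def enrich_subgraph(subgraph_genes: frozenset, annotations: AnnotationMap,
                    network_genes: set, min_term_genes: int = 2) -> pd.DataFrame:
    """Raw (uncorrected) per-term enrichment of a single subgraph."""
    terms = eligible_terms(annotations, network_genes, min_term_genes)
    rows = []
    n_net = len(network_genes)
    size = len(subgraph_genes)
    for term in sorted(terms):
        genes = terms[term]
        tp = len(subgraph_genes & genes)
        fp = size - tp
        fn = len(genes) - tp
        tn = n_net - size - fn
        rows.append({
            "term": term, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "p": stats.hypergeom_sf(tp, n_net, len(genes), size),
            "mcc": stats.mcc(tp, fp, fn, tn),
        })
    return pd.DataFrame(rows, columns=["term", "tp", "fp", "fn", "tn", "p", "mcc"])


def enrich_catalogue(subgraphs, annotations: AnnotationMap, network_genes: set,
                     fdr_alpha: float = 0.05, min_term_genes: int = 2,
                     bh_scope: str = "run") -> pd.DataFrame:
    """Enrichment of every subgraph of a network in one BH pool.

    ``subgraphs`` maps subgraph id -> gene frozenset (or is an iterable of
    objects with .id and .genes). Tests are computed for every (subgraph,
    eligible term) pair with a non-empty intersection; BH correction pools
    across the whole run (``bh_scope='run'``) or within each subgraph
    (``bh_scope='per_subgraph'``). Returns a DataFrame with columns
    subgraph, term, tp, fp, fn, tn, p, q, mcc, enriched.
    """
    if bh_scope not in ("run", "per_subgraph"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    if not isinstance(subgraphs, dict):
        subgraphs = {s.id: s.genes for s in subgraphs}
    terms_map = eligible_terms(annotations, network_genes, min_term_genes)
    cols = ["subgraph", "term", "tp", "fp", "fn", "tn", "p", "q", "mcc", "enriched"]
    if not subgraphs or not terms_map:
        return pd.DataFrame(columns=cols)

    sub_ids = sorted(subgraphs)
    term_ids = sorted(terms_map)
    genes = sorted(network_genes, key=str)
    gidx = {g: i for i, g in enumerate(genes)}

    def incidence(sets):
        rows, colixs = [], []
        for i, members in enumerate(sets):
            for g in members:
                j = gidx.get(g)
                if j is not None:
                    rows.append(i)
                    colixs.append(j)
        return csr_matrix((np.ones(len(rows), dtype=np.int64), (rows, colixs)),
                          shape=(len(sets), len(genes)))

    S = incidence([subgraphs[s] for s in sub_ids])
    T = incidence([terms_map[t] for t in term_ids])
    tp = np.asarray((S @ T.T).todense(), dtype=np.int64)  # subs x terms
    sizes = np.asarray(S.sum(axis=1)).ravel()
    kterm = np.asarray(T.sum(axis=1)).ravel()
    # single-gene overlaps can never reach significance (p >= K/N ~ 0.01 at
    # q-rank 1 of a grid-sized family); materialise tp >= 2 rows only
    ii, jj = np.nonzero(tp >= 2)
    n_net = len(genes)
    tpv = tp[ii, jj]
    fpv = sizes[ii] - tpv
    fnv = kterm[jj] - tpv
    tnv = n_net - sizes[ii] - fnv
    pv = np.atleast_1d(stats.hypergeom_sf_array(tpv, n_net, kterm[jj], sizes[ii]))
    mccv = stats.mcc_array(tpv, fpv, fnv, tnv)
    df = pd.DataFrame({
        "subgraph": [sub_ids[i] for i in ii],
        "term": [term_ids[j] for j in jj],
        "tp": tpv, "fp": fpv, "fn": fnv, "tn": tnv,
        "p": pv, "mcc": mccv,
    }).sort_values(["subgraph", "term"], kind="mergesort", ignore_index=True)
    # the BH family is the full subgraph x eligible-term grid; pairs with an
    # empty intersection (p = 1) are part of the family even though they are
    # not materialised as rows
    if bh_scope == "run":
        df["q"] = stats.bh_qvalues(df["p"].to_numpy(),
                                   n_tests=len(sub_ids) * len(term_ids))
    else:
        df["q"] = df.groupby("subgraph")["p"].transform(
            lambda s: stats.bh_qvalues(s.to_numpy(), n_tests=len(term_ids)))
    df["enriched"] = df["q"] < fdr_alpha
    return df[cols]


@dataclass
class CoverageReport:
    """Per-namespace enriched/total term counts, coverage % and mean (over
    enriched terms) of the best per-term MCC."""

    per_namespace: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for ns in NAMESPACES:
            if ns in self.per_namespace:
                rows.append({"namespace": ns, **self.per_namespace[ns]})
        return pd.DataFrame(rows)


def coverage(enrichments: pd.DataFrame, annotations: AnnotationMap,
             ontology: Ontology, network_genes: set,
             min_term_genes: int = 2) -> CoverageReport:
    """Ontology coverage of one network's enrichment run."""
    terms_map = eligible_terms(annotations, network_genes, min_term_genes)
    enriched = enrichments[enrichments["enriched"]] if len(enrichments) else enrichments
    best_mcc = (enriched.groupby("term")["mcc"].max()
                if len(enriched) else pd.Series(dtype=float))
    report = CoverageReport()
    for ns in NAMESPACES:
        ns_terms = sorted(t for t in terms_map if ontology.namespaces[t] == ns)
        ns_enriched = [t for t in ns_terms if t in best_mcc.index]
        total = len(ns_terms)
        hit = len(ns_enriched)
        report.per_namespace[ns] = {
            "enriched_terms": hit,
            "total_terms": total,
            "coverage_pct": 100.0 * hit / total if total else 0.0,
            "average_mcc": float(best_mcc.loc[ns_enriched].mean()) if hit else 0.0,
            "no_enriched_terms": hit == 0,
        }
    return report


def enriched_term_pairs(enrichments: pd.DataFrame) -> set:
    """Unordered pairs of terms co-enriched in at least one subgraph."""
    pairs = set()
    if len(enrichments) == 0:
        return pairs
    enr = enrichments[enrichments["enriched"]]
    for _, terms in enr.groupby("subgraph")["term"]:
        for t1, t2 in itertools.combinations(sorted(terms), 2):
            pairs.add((t1, t2))
    return pairs


def classify_pairs(pairs: set, ontology: Ontology) -> pd.DataFrame:
    """Classify co-enriched pairs: same-namespace related (ancestor or
    descendant), same-namespace unrelated, or different namespace."""
    counts = {"same_ontology_related": 0, "same_ontology_unrelated": 0,
              "different_ontology": 0}
    for t1, t2 in pairs:
        if ontology.namespaces[t1] != ontology.namespaces[t2]:
            counts["different_ontology"] += 1
        elif ontology.related(t1, t2):
            counts["same_ontology_related"] += 1
        else:
            counts["same_ontology_unrelated"] += 1
    total = sum(counts.values())
    rows = [{"class": k, "count": v,
             "pct": 100.0 * v / total if total else 0.0}
            for k, v in counts.items()]
    rows.insert(0, {"class": "all", "count": total, "pct": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


def coenrichment_pairs(per_network_enrichments: dict, ontology: Ontology,
                       merged_enrichments: pd.DataFrame | None = None):
    """Co-enrichment tables per network plus the novel-pair report.

    ``per_network_enrichments`` maps network name -> enrichment DataFrame.
    Novel pairs are co-enriched in the merged reciprocal-best-hit
    subnetworks but in no single network's subgraphs.
    """
    tables = {}
    single_pairs: set = set()
    for name in sorted(per_network_enrichments):
        pairs = enriched_term_pairs(per_network_enrichments[name])
        single_pairs |= pairs
        tables[name] = classify_pairs(pairs, ontology)
    novel = set()
    if merged_enrichments is not None:
        merged_pairs = enriched_term_pairs(merged_enrichments)
        novel = merged_pairs - single_pairs
        tables["merged_reciprocal"] = classify_pairs(merged_pairs, ontology)
        tables["novel_pairs"] = classify_pairs(novel, ontology)
    return tables, sorted(novel)


def randomize_annotations(annotations: AnnotationMap, seed: int,
                          universe=None) -> AnnotationMap:
    """Permute gene labels over annotation profiles.

    Every annotation profile (a gene's term set) is reassigned to a gene
    drawn without replacement from ``universe`` (default: the annotated
    genes), preserving the multiset of per-gene annotation counts and every
    term's total usage while destroying the gene-to-structure alignment.
    """
    if not annotations.gene_terms:
        raise ValueError("cannot randomize an empty annotation map")
    profiles = [annotations.gene_terms[g] for g in sorted(annotations.gene_terms, key=str)]
    pool = sorted(universe, key=str) if universe is not None else \
        sorted(annotations.gene_terms, key=str)
    if len(pool) < len(profiles):
        raise ValueError("universe smaller than the number of annotation profiles")
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(len(pool))[:len(profiles)]
    return AnnotationMap({pool[int(i)]: prof for i, prof in zip(chosen, profiles)})


def relative_enrichment_by_term_size(enrichments: pd.DataFrame,
                                     annotations: AnnotationMap,
                                     network_genes: set,
                                     bins=(2, 4, 8, 16, 32, 64, 128),
                                     mcc_threshold: float = 0.2,
                                     min_term_genes: int = 2) -> pd.DataFrame:
    """Proportion of enriched terms per term-size bin minus the proportion of
    all eligible terms in that bin (bin values sum to zero).

    Only enrichments whose best MCC reaches ``mcc_threshold`` count. Bin
    edges are lower bounds; the last bin is open-ended.
    """
    terms_map = eligible_terms(annotations, network_genes, min_term_genes)
    sizes = {t: len(g) for t, g in terms_map.items()}
    enr = enrichments[enrichments["enriched"]]
    best = enr.groupby("term")["mcc"].max()
    passing = [t for t in best.index if best[t] >= mcc_threshold and t in sizes]
    if not passing:
        raise ValueError("no enriched term passes the MCC threshold")
    edges = list(bins) + [np.inf]

    def proportions(term_list):
        counts = np.zeros(len(bins), dtype=float)
        for t in term_list:
            s = sizes[t]
            for b in range(len(bins)):
                if edges[b] <= s < edges[b + 1]:
                    counts[b] += 1
                    break
        return counts / counts.sum()

    p_enr = proportions(passing)
    p_all = proportions(sorted(sizes))
    return pd.DataFrame({
        "bin_min_size": list(bins),
        "enriched_proportion": p_enr,
        "overall_proportion": p_all,
        "relative_enrichment": p_enr - p_all,
    })
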