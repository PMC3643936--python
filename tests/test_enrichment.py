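import math

import numpy as np
import pandas as pd
import pytest

from modulenet import stats
from modulenet.enrichment import (
    AnnotationMap,
    Ontology,
    classify_pairs,
    coenrichment_pairs,
    coverage,
    eligible_terms,
    enrich_catalogue,
    enrich_subgraph,
    enriched_term_pairs,
    load_ontology_and_annotations,
    randomize_annotations,
    read_annotations,
    relative_enrichment_by_term_size,
)

OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: mid process
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf process
namespace: biological_process
relationship: part_of GO:0000002

[Term]
id: GO:0000010
name: root function
namespace: molecular_function
"""

GAF = """!gene\tterm\tevidence
g1\tGO:0000003\tIDA
g2\tGO:0000003\tIEA
g3\tGO:0000002\tIMP
g4\tGO:0000010\tIEA
"""


@pytest.fixture()
def tiny_files(tmp_path):
    obo = tmp_path / "t.obo"
    obo.write_text(OBO)
    gaf = tmp_path / "t.tsv"
    gaf.write_text(GAF)
    return obo, gaf


class TestLoading:
    def test_true_path_propagation(self, tiny_files):
        ontology, ann = load_ontology_and_annotations(*tiny_files)
        assert ann.gene_terms["g1"] == {"GO:0000003", "GO:0000002", "GO:0000001"}
        assert ann.gene_terms["g3"] == {"GO:0000002", "GO:0000001"}

    def test_part_of_counts_as_parent(self, tiny_files):
        ontology, _ = load_ontology_and_annotations(*tiny_files)
        assert "GO:0000002" in ontology.ancestors("GO:0000003")

    def test_evidence_mode_filters(self, tiny_files):
        obo, gaf = tiny_files
        no_iea = read_annotations(gaf, mode="no_iea")
        assert "g2" not in no_iea.gene_terms and "g4" not in no_iea.gene_terms
        only_iea = read_annotations(gaf, mode="only_iea")
        assert set(only_iea.gene_terms) == {"g2", "g4"}

    def test_empty_annotation_file(self, tmp_path):
        gaf = tmp_path / "empty.tsv"
        gaf.write_text("!gene\tterm\tevidence\n")
        assert read_annotations(gaf).gene_terms == {}

    def test_cyclic_ontology_rejected(self):
        with pytest.raises(ValueError):
            Ontology({"a": "biological_process", "b": "biological_process"},
                     {"a": {"b"}, "b": {"a"}})

    def test_unknown_namespace_rejected(self):
        with pytest.raises(ValueError):
            Ontology({"a": "mystery_process"}, {})


def flat_ontology(terms, ns="biological_process"):
    return Ontology({t: ns for t in terms}, {})


class TestEnrich:
    def test_closed_form_exact_capture(self):
        network = {f"g{i}" for i in range(100)}
        term_genes = {f"g{i}" for i in range(10)}
        ann = AnnotationMap({g: frozenset({"T"}) for g in term_genes})
        df = enrich_subgraph(frozenset(term_genes), ann, network)
        row = df.iloc[0]
        assert row["p"] == pytest.approx(1 / math.comb(100, 10))
        assert (row["tp"], row["fp"], row["fn"], row["tn"]) == (10, 0, 0, 90)
        assert row["mcc"] == pytest.approx(1.0)

    def test_term_annotating_everything_scores_zero_mcc(self):
        network = {f"g{i}" for i in range(20)}
        ann = AnnotationMap({g: frozenset({"T"}) for g in network})
        df = enrich_subgraph(frozenset(list(network)[:5]), ann, network)
        assert df.iloc[0]["mcc"] == 0.0

    def test_disjoint_subgraph_p_one(self):
        network = {f"g{i}" for i in range(30)}
        ann = AnnotationMap({g: frozenset({"T"}) for g in list(network)[:4]})
        sub = frozenset(sorted(network)[10:15]) - set(list(network)[:4])
        df = enrich_subgraph(sub, ann, network)
        assert df.iloc[0]["tp"] == 0
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_enumeration_small_universes(self):
        for m in (10, 18, 25):
            network = {f"g{i}" for i in range(m)}
            for k in (2, 5, 9):
                term_genes = {f"g{i}" for i in range(k)}
                ann = AnnotationMap({g: frozenset({"T"}) for g in term_genes})
                for s in (3, 7):
                    sub = frozenset(f"g{i}" for i in range(m - s, m))
                    tp = len(sub & term_genes)
                    df = enrich_subgraph(sub, ann, network)
                    expected = sum(
                        math.comb(k, j) * math.comb(m - k, s - j)
                        for j in range(tp, min(k, s) + 1)) / math.comb(m, s)
                    assert df.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)

    def test_catalogue_grid_family_and_shared_mcc(self):
        network = {f"g{i}" for i in range(50)}
        term_a = frozenset(f"g{i}" for i in range(8))
        term_b = frozenset(f"g{i}" for i in range(20, 26))
        ann = AnnotationMap({g: frozenset({"A"}) for g in term_a}
                            | {g: frozenset({"B"}) for g in term_b})
        subs = {"s1": term_a, "s2": frozenset(list(term_b)[:3]) | {"g40", "g41"}}
        df = enrich_catalogue(subs, ann, network, fdr_alpha=0.05)
        # q uses the full 2x2 grid (2 subgraphs x 2 terms = 4 tests)
        row = df[(df.subgraph == "s1") & (df.term == "A")].iloc[0]
        assert row["q"] == pytest.approx(min(1.0, row["p"] * 4 / 1))
        for _, r in df.iterrows():
            assert r["mcc"] == pytest.approx(
                stats.mcc(r["tp"], r["fp"], r["fn"], r["tn"]))

    def test_eligibility_floor(self):
        network = {"g1", "g2", "g3"}
        ann = AnnotationMap({"g1": frozenset({"solo"}),
                             "g2": frozenset({"pair"}), "g3": frozenset({"pair"})})
        assert set(eligible_terms(ann, network)) == {"pair"}


class TestCoverage:
    def make_enrichments(self, rows):
        return pd.DataFrame(rows, columns=["subgraph", "term", "tp", "fp", "fn",
                                           "tn", "p", "q", "mcc", "enriched"])

    def test_three_of_four_terms(self):
        onto = flat_ontology(["t1", "t2", "t3", "t4"])
        ann = AnnotationMap({f"g{i}{t}": frozenset({t}) for t in onto.terms
                             for i in range(2)})
        enr = self.make_enrichments(
            [("s", t, 2, 0, 0, 0, 1e-9, 1e-8, 0.5, True) for t in ("t1", "t2", "t3")])
        rep = coverage(enr, ann, onto, ann.genes())
        bp = rep.per_namespace["biological_process"]
        assert bp["coverage_pct"] == pytest.approx(75.0)
        assert bp["enriched_terms"] == 3 and bp["total_terms"] == 4

    def test_no_enrichment_flagged(self):
        onto = flat_ontology(["t1"])
        ann = AnnotationMap({"g1": frozenset({"t1"}), "g2": frozenset({"t1"})})
        rep = coverage(self.make_enrichments([]), ann, onto, ann.genes())
        bp = rep.per_namespace["biological_process"]
        assert bp["coverage_pct"] == 0.0 and bp["no_enriched_terms"]

    def test_average_mcc_is_max_then_mean(self):
        onto = flat_ontology(["t1"])
        ann = AnnotationMap({f"g{i}": frozenset({"t1"}) for i in range(2)})
        enr = self.make_enrichments([
            ("s1", "t1", 2, 0, 0, 0, 1e-9, 1e-8, 0.3, True),
            ("s2", "t1", 2, 0, 0, 0, 1e-9, 1e-8, 0.9, True)])
        rep = coverage(enr, ann, onto, ann.genes())
        assert rep.per_namespace["biological_process"]["average_mcc"] == pytest.approx(0.9)


class TestCoenrichment:
    def onto(self):
        return Ontology(
            {"r": "biological_process", "t": "biological_process",
             "u": "biological_process", "f": "molecular_function"},
            {"t": {"r"}})

    def enr(self, sub_terms):
        rows = [(s, t, 2, 0, 0, 0, 1e-9, 1e-8, 0.5, True)
                for s, terms in sub_terms.items() for t in terms]
        return pd.DataFrame(rows, columns=["subgraph", "term", "tp", "fp", "fn",
                                           "tn", "p", "q", "mcc", "enriched"])

    def test_pair_classes(self):
        onto = self.onto()
        df = classify_pairs({("r", "t"), ("t", "u"), ("f", "t")}, onto)
        counts = dict(zip(df["class"], df["count"]))
        assert counts["same_ontology_related"] == 1
        assert counts["same_ontology_unrelated"] == 1
        assert counts["different_ontology"] == 1

    def test_pairs_require_cooccurrence(self):
        pairs = enriched_term_pairs(self.enr({"s1": ["t", "r"], "s2": ["u"]}))
        assert pairs == {("r", "t")}

    def test_novel_pairs_are_set_difference(self):
        onto = self.onto()
        single = {"net1": self.enr({"s1": ["t", "r"]})}
        merged = self.enr({"m1": ["t", "u"], "m2": ["t", "r"]})
        tables, novel = coenrichment_pairs(single, onto, merged_enrichments=merged)
        assert novel == [("t", "u")]
        assert "novel_pairs" in tables


class TestRandomize:
    def test_single_profile_unchanged(self):
        ann = AnnotationMap({"g1": frozenset({"t"})})
        assert randomize_annotations(ann, seed=3).gene_terms == ann.gene_terms

    def test_profile_multiset_and_term_totals_preserved(self):
        ann = AnnotationMap({"g1": frozenset({"a", "b", "c"}),
                             "g2": frozenset({"a"}),
                             "g3": frozenset({"b", "c"})})
        rand = randomize_annotations(ann, seed=11, universe={f"g{i}" for i in range(9)})
        sizes = sorted(len(t) for t in rand.gene_terms.values())
        assert sizes == [1, 2, 3]
        assert rand.term_genes().keys() == ann.term_genes().keys()
        for t, members in ann.term_genes().items():
            assert len(rand.term_genes()[t]) == len(members)

    def test_deterministic_per_seed(self):
        ann = AnnotationMap({f"g{i}": frozenset({f"t{i % 3}"}) for i in range(20)})
        a = randomize_annotations(ann, seed=5)
        b = randomize_annotations(ann, seed=5)
        assert a.gene_terms == b.gene_terms

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            randomize_annotations(AnnotationMap({}), seed=0)


class TestRelativeEnrichment:
    def setup_terms(self, sizes):
        ann = {}
        for t, size in sizes.items():
            for i in range(size):
                ann.setdefault(f"g_{t}_{i}", set()).add(t)
        return AnnotationMap({g: frozenset(ts) for g, ts in ann.items()})

    def enr(self, terms, mcc=0.9):
        rows = [("s", t, 2, 0, 0, 0, 1e-9, 1e-8, mcc, True) for t in terms]
        return pd.DataFrame(rows, columns=["subgraph", "term", "tp", "fp", "fn",
                                           "tn", "p", "q", "mcc", "enriched"])

    def test_identical_distributions_zero(self):
        ann = self.setup_terms({"t1": 3, "t2": 3})
        df = relative_enrichment_by_term_size(self.enr(["t1", "t2"]), ann,
                                              ann.genes(), bins=(2, 4))
        assert np.allclose(df["relative_enrichment"], 0.0)

    def test_concentration_in_small_bin(self):
        ann = self.setup_terms({"t1": 3, "t2": 8})
        df = relative_enrichment_by_term_size(self.enr(["t1"]), ann,
                                              ann.genes(), bins=(2, 6))
        assert df["relative_enrichment"].tolist() == pytest.approx([0.5, -0.5])

    def test_values_sum_to_zero(self):
        ann = self.setup_terms({"t1": 3, "t2": 5, "t3": 9, "t4": 20})
        df = relative_enrichment_by_term_size(self.enr(["t2", "t3"]), ann,
                                              ann.genes())
        assert abs(df["relative_enrichment"].sum()) < 1e-12

    def test_mcc_threshold_filters(self):
        ann = self.setup_terms({"t1": 3})
        with pytest.raises(ValueError):
            relative_enrichment_by_term_size(self.enr(["t1"], mcc=0.1), ann,
                                             ann.genes(), mcc_threshold=0.2)
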