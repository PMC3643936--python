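import math

import networkx as nx
import numpy as np
import pytest

from modulenet.congruence import (
    CongruenceHit,
    OverlapCounts,
    build_best_hit_graph,
    call_best_hits,
    high_degree,
    high_degree_neighbourhoods,
    mcc,
    merge_subgraphs,
    overlap_test,
    reciprocal_best_hits,
    score_layer_pair,
)
from modulenet.netio import Network
from modulenet import stats
from tests.conftest import make_subgraph


def genes(prefix, n):
    return [f"{prefix}{i:02d}" for i in range(n)]


class TestMCC:
    def test_worked_values(self):
        assert mcc(OverlapCounts(tp=5, fp=0, fn=0, tn=5)) == pytest.approx(1.0)
        assert mcc((8, 2, 2, 2)) == pytest.approx(0.3)
        assert mcc((0, 3, 3, 0)) == pytest.approx(-1.0)

    def test_zero_denominator_is_zero(self):
        assert mcc((0, 0, 3, 3)) == 0.0

    def test_identical_sets_score_perfect(self):
        c = OverlapCounts.from_gene_sets(set("abcde"), set("abcde"))
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 0)
        assert mcc(c) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mcc((0, 0, 0, 0))

    def test_symmetry_under_role_swap_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tp, fp, fn, tn = rng.integers(0, 100, size=4)
            if tp + fp + fn + tn == 0:
                continue
            assert mcc((tp, fp, fn, tn)) == pytest.approx(mcc((tp, fn, fp, tn)))

    def test_counts_from_gene_sets(self):
        c = OverlapCounts.from_gene_sets(set("abcde"), set("cdefg"))
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 2, 2, 4)


class TestOverlapTest:
    def test_closed_form_complete_overlap(self):
        a = make_subgraph(genes("g", 5), layer="ppi")
        b = make_subgraph(genes("g", 5), layer="genetic")
        universe = set(genes("g", 5)) | set(genes("u", 15))
        hit = overlap_test(a, b, universe)
        assert hit.p == pytest.approx(1 / math.comb(20, 5))
        assert hit.mcc == pytest.approx(1.0)

    def test_disjoint_pair_filtered(self):
        a = make_subgraph(genes("a", 5), layer="ppi")
        b = make_subgraph(genes("b", 5), layer="genetic")
        assert overlap_test(a, b, set(genes("a", 5) + genes("b", 5))) is None

    def test_tenfold_size_filter(self):
        a = make_subgraph(genes("g", 3), layer="ppi")
        big = make_subgraph(genes("g", 3) + genes("u", 28), layer="genetic")
        assert overlap_test(a, big, set(genes("g", 3) + genes("u", 50))) is None

    def test_same_layer_rejected(self):
        a = make_subgraph(genes("g", 5), layer="ppi")
        b = make_subgraph(genes("g", 5), layer="ppi")
        with pytest.raises(ValueError):
            overlap_test(a, b, set(genes("g", 30)))

    def test_small_universe_rejected(self):
        a = make_subgraph(genes("g", 5), layer="ppi")
        b = make_subgraph(genes("g", 5), layer="genetic")
        with pytest.raises(ValueError):
            overlap_test(a, b, set(genes("g", 4)))

    def test_literal_union_population(self):
        a = make_subgraph(genes("g", 4) + ["x0"], layer="ppi")
        b = make_subgraph(genes("g", 4) + ["y0"], layer="genetic")
        hit = overlap_test(a, b, set(genes("g", 30)), mode="literal_union")
        # population = |A u B| = 6, successes 5, draws 5, tp 4
        assert hit.p == pytest.approx(stats.hypergeom_sf(4, 6, 5, 5))

    def test_matches_enumeration_small_universes(self):
        """Upper-tail probabilities agree with exhaustive enumeration on a
        grid of overlap configurations."""
        for m in (12, 20, 25):
            for size_a in (3, 5, 8):
                for size_b in (3, 6):
                    for tp in range(max(1, size_a + size_b - m),
                                    min(size_a, size_b) + 1):
                        shared = genes("s", tp)
                        a = make_subgraph(shared + genes("a", size_a - tp), "ppi")
                        b = make_subgraph(shared + genes("b", size_b - tp), "genetic")
                        universe = set(genes("s", tp) + genes("a", size_a - tp)
                                       + genes("b", size_b - tp)
                                       + genes("u", m - len(a.genes | b.genes)))
                        hit = overlap_test(a, b, universe, n_min=1, m_min=-1.0,
                                           max_ratio=100.0)
                        expected = sum(
                            math.comb(size_a, j) * math.comb(m - size_a, size_b - j)
                            for j in range(tp, min(size_a, size_b) + 1)
                        ) / math.comb(m, size_b)
                        assert hit.p == pytest.approx(expected, rel=1e-9)


class TestBestHits:
    def hit(self, a, b, la, lb, mcc_, p):
        return CongruenceHit(a, b, la, lb, 5, 5,
                             OverlapCounts(3, 2, 2, 4), mcc_, p)

    def test_bh_worked_example(self):
        hits = [self.hit(f"a{i}", f"b{i}", "x", "y", 0.5, p)
                for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        out = call_best_hits(hits, fdr_alpha=0.05)
        assert all(h.q == pytest.approx(0.04) for h in out)

    def test_argmax_mcc_flagging(self):
        strong = self.hit("A", "B", "x", "y", 0.9, 1e-8)
        weak = self.hit("A", "C", "x", "y", 0.4, 1e-8)
        out = call_best_hits([strong, weak])
        strong = [h for h in out if h.subgraph_b == "B"][0]
        weak = [h for h in out if h.subgraph_b == "C"][0]
        assert strong.best_a_to_b and not weak.best_a_to_b
        assert strong.best_b_to_a and weak.best_b_to_a  # B's and C's own bests

    def test_reciprocal_definition(self):
        ab = self.hit("A", "B", "x", "y", 0.9, 1e-9)
        ac = self.hit("A", "C", "x", "y", 0.5, 1e-9)
        cb = self.hit("D", "C", "x", "y", 0.8, 1e-9)
        out = call_best_hits([ab, ac, cb])
        rec = {(h.subgraph_a, h.subgraph_b) for h in reciprocal_best_hits(out)}
        assert ("A", "B") in rec
        assert ("A", "C") not in rec

    def test_insignificant_hits_never_flagged(self):
        out = call_best_hits([self.hit("A", "B", "x", "y", 0.9, 0.9)])
        assert not out[0].best_a_to_b and not out[0].best_b_to_a

    def test_bh_monotonicity_fuzz(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            q = stats.bh_qvalues(p)
            assert (q >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()


class TestScoreLayerPair:
    def test_matches_single_pair_scoring(self):
        rng = np.random.default_rng(3)
        pool = genes("g", 40)
        subs_a = [make_subgraph(rng.choice(pool, size=s, replace=False), "ppi",
                                sid=f"a{i}")
                  for i, s in enumerate([5, 8, 12])]
        subs_b = [make_subgraph(rng.choice(pool, size=s, replace=False), "genetic",
                                sid=f"b{i}")
                  for i, s in enumerate([6, 9])]
        universe = set(pool)
        hits = score_layer_pair(subs_a, subs_b, universe, n_min=1, m_min=-1.0)
        assert hits, "expected at least one scored pair"
        for h in hits:
            a = next(s for s in subs_a if s.id == h.subgraph_a)
            b = next(s for s in subs_b if s.id == h.subgraph_b)
            single = overlap_test(a, b, universe, n_min=1, m_min=-1.0)
            assert h.p == pytest.approx(single.p)
            assert h.mcc == pytest.approx(single.mcc)
            assert h.counts == single.counts


class TestBestHitGraph:
    def hit(self, a, b, flag_ab=True, flag_ba=False):
        h = CongruenceHit(a, b, "x", "y", 5, 5, OverlapCounts(3, 2, 2, 4),
                          0.5, 1e-6, q=1e-5)
        h.best_a_to_b, h.best_b_to_a = flag_ab, flag_ba
        return h

    def test_degree_counts_incident_best_hits(self):
        hits = [self.hit("X", f"b{i}") for i in range(3)]
        g = build_best_hit_graph(hits)
        assert g.degree("X") == 3

    def test_percentile_cutoff(self):
        hits = [self.hit("hub", f"b{i}") for i in range(9)]
        hits += [self.hit(f"s{i}", f"t{i}") for i in range(4)]
        g = build_best_hit_graph(hits)
        # degrees: hub 9, everything else 1
        assert high_degree(g, percentile=90.0) == ["hub"]

    def test_empty_graph(self):
        assert high_degree(nx.Graph()) == []

    def test_neighbourhood_membership(self):
        hits = [self.hit("hub", f"b{i}") for i in range(3)]
        g = build_best_hit_graph(hits)
        members = high_degree_neighbourhoods(g, ["hub"])
        assert members == {"hub", "b0", "b1", "b2"}


class TestMerge:
    def rbh(self, a, b):
        h = CongruenceHit(a.id, b.id, a.source_layer, b.source_layer,
                          a.size(), b.size(),
                          OverlapCounts.from_gene_sets(a.genes, b.genes),
                          0.9, 1e-9, q=1e-8)
        h.best_a_to_b = h.best_b_to_a = True
        return h

    def test_path_betweenness(self):
        a = make_subgraph(["a", "b", "c"], "ppi")
        b = make_subgraph(["a", "b", "c"], "genetic")
        layers = [Network.from_edges("ppi", [("a", "b"), ("b", "c")]),
                  Network.from_edges("genetic", [("a", "b")])]
        merged = merge_subgraphs(a, b, layers, self.rbh(a, b))
        assert merged.node_betweenness["b"] == pytest.approx(1.0)

    def test_star_centre_betweenness(self):
        nodes = ["hub", "l1", "l2", "l3", "l4"]
        a = make_subgraph(nodes, "ppi")
        b = make_subgraph(nodes, "genetic")
        star = [("hub", leaf) for leaf in nodes[1:]]
        layers = [Network.from_edges("ppi", star),
                  Network.from_edges("genetic", star[:2])]
        merged = merge_subgraphs(a, b, layers, self.rbh(a, b))
        assert merged.node_betweenness["hub"] == pytest.approx(6.0)

    def test_layer_tags_preserved(self):
        a = make_subgraph(["a", "b", "c"], "ppi")
        b = make_subgraph(["a", "b", "c"], "genetic")
        layers = [Network.from_edges("ppi", [("a", "b"), ("b", "c")]),
                  Network.from_edges("genetic", [("a", "b"), ("a", "c")])]
        merged = merge_subgraphs(a, b, layers, self.rbh(a, b))
        assert merged.graph["a"]["b"]["layers"] == ("genetic", "ppi")
        assert merged.graph["b"]["c"]["layers"] == ("ppi",)

    def test_non_reciprocal_rejected(self):
        a = make_subgraph(["a", "b", "c"], "ppi")
        b = make_subgraph(["a", "b", "c"], "genetic")
        bad = self.rbh(a, b)
        bad.best_b_to_a = False
        with pytest.raises(ValueError):
            merge_subgraphs(a, b, [], bad)
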