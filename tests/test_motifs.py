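"""Triad classification, census, switching null and motif significance."""

import itertools
import math

import pytest

from conftest import oracle_census, oracle_triad_canonical
from eetnet import motifs as mt
from eetnet import synthetic as syn
from eetnet.network import IntegratedNetwork, RegArc, ScoredEdge


def mixed(ppi=(), arcs=()):
    return IntegratedNetwork(
        ppi_edges=[ScoredEdge(a, b, 0.9) for a, b in ppi],
        reg_arcs=[RegArc(u, v) for u, v in arcs])


class TestClassifyTriad:
    def test_named_taxonomy_examples(self):
        clique = {(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)}
        assert mt.classify_triad(clique).name == "Protein Clique"
        co_reg = {(0, 1), (0, 2)}
        assert mt.classify_triad(co_reg).name == "Co-regulated Proteins"
        co_reg_ppi = {(0, 1), (0, 2), (1, 2), (2, 1)}
        assert mt.classify_triad(co_reg_ppi).name == "Co-regulated PPI"

    def test_disconnected_triple_rejected(self):
        with pytest.raises(ValueError, match="not connected"):
            mt.classify_triad({(0, 1), (1, 0)})

    def test_classification_invariant_under_relabeling(self):
        # exhaustive over all 64 patterns and all 6 node orderings
        pairs = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))
        for code in range(64):
            arcs = {p for i, p in enumerate(pairs) if code & (1 << i)}
            try:
                base = mt.classify_triad(arcs)
            except ValueError:
                continue
            for perm in itertools.permutations(range(3)):
                relabeled = {(perm[i], perm[j]) for i, j in arcs}
                assert mt.classify_triad(relabeled).code == base.code

    def test_the_13_connected_classes_are_distinct(self):
        assert len({c.code for c in mt.TRIAD_CLASSES}) == 13
        for cls in mt.TRIAD_CLASSES:
            assert mt.classify_triad(set(cls.example)).code == cls.code
            assert oracle_triad_canonical(set(cls.example)) == cls.code


class TestCensus:
    def test_single_ppi_triangle(self):
        counts = mt.census(mixed(ppi=[("a", "b"), ("b", "c"), ("a", "c")]))
        assert counts == {mt.CLASS_BY_NAME["Protein Clique"].code: 1}

    def test_ppi_star_closed_form(self):
        counts = mt.census(mixed(ppi=[("h", "a"), ("h", "b"), ("h", "c")]))
        assert counts == {mt.CLASS_BY_NAME["PPI Chain"].code: 3}

    def test_matches_all_triples_oracle_on_random_mixed_graph(
            self, random_mixed_network):
        assert dict(mt.census(random_mixed_network)) == oracle_census(
            random_mixed_network)

    def test_hybrid_pairs_collapse_to_ppi_with_warning(self):
        net = mixed(ppi=[("a", "b"), ("b", "c")], arcs=[("a", "b")])
        with pytest.warns(UserWarning, match="both a PPI edge"):
            g = mt.MixedDigraph.from_network(net)
        assert g.hybrid_fraction == pytest.approx(0.5)
        assert mt.census(g) == {mt.CLASS_BY_NAME["PPI Chain"].code: 1}


class TestRandomize:
    def test_single_edge_has_no_swap_partner(self):
        g = mt.MixedDigraph.from_network(mixed(ppi=[("a", "b")]))
        r = mt.randomize(g, seed=0)
        assert r.mutual == g.mutual and r.single == g.single

    def test_degree_triples_preserved(self, random_mixed_network):
        g = mt.MixedDigraph.from_network(random_mixed_network)
        r = mt.randomize(g, seed=5)
        for node in g.succ:
            assert g.degree_triple(node) == r.degree_triple(node)
        assert len(r.mutual) == len(g.mutual)
        assert len(r.single) == len(g.single)

    def test_no_self_loops_or_hybrid_pairs_created(self, random_mixed_network):
        g = mt.MixedDigraph.from_network(random_mixed_network)
        r = mt.randomize(g, seed=9)
        for u, v in r.single:
            assert u != v
            assert (v, u) not in r.single          # no accidental mutual
            assert frozenset((u, v)) not in r.mutual
        for pair in r.mutual:
            assert len(pair) == 2

    @pytest.mark.parametrize("seed_block", [0, 1])
    def test_switching_mixes_the_edge_set(self, seed_block):
        edges = syn.generate_interactome(120, 3.4, seed=13)
        assert len(edges) > 150
        g = mt.MixedDigraph.from_network(
            IntegratedNetwork(ppi_edges=edges))
        ok = 0
        for seed in range(10 * seed_block, 10 * seed_block + 10):
            r = mt.randomize(g, seed=seed)
            inter = len(g.mutual & r.mutual)
            union = len(g.mutual | r.mutual)
            if inter / union < 0.5:
                ok += 1
        assert ok >= 9


class TestMotifSignificance:
    def test_z_is_zero_p_is_one_when_null_equals_real(self):
        # a PPI triangle admits no legal swap: every null equals the real
        net = mixed(ppi=[("a", "b"), ("b", "c"), ("a", "c")])
        stats = mt.motif_significance(net, n_random=10, seed=0)
        (s,) = stats
        assert s.z_score == 0.0 and s.p_value == 1.0

    def test_z_recomputable_from_reported_triple(self, random_mixed_network):
        for s in mt.motif_significance(random_mixed_network, n_random=20,
                                       n_swaps=2000, seed=1):
            if s.null_sd > 0:
                expect = (s.real_count - s.null_mean) / s.null_sd
                assert s.z_score == pytest.approx(expect, abs=1e-9)
            else:
                assert s.z_score in (0.0, math.inf, -math.inf)

    def test_planted_feedforward_excess_detected(self):
        edges = syn.generate_interactome(60, 2.5, seed=5)
        arcs = syn.generate_regulon(8, 5,
                                    [f"SYN_{i:04d}" for i in range(60)],
                                    seed=6)
        net = IntegratedNetwork(ppi_edges=edges, reg_arcs=arcs)
        planted, truth = syn.plant_motifs(net, "Feedforward Loop", 20, seed=7)
        code = mt.CLASS_BY_NAME["Feedforward Loop"].code
        hits = 0
        for seed in range(5):
            stats = {s.code: s for s in mt.motif_significance(
                planted, n_random=100, seed=seed)}
            s = stats[code]
            if s.z_score > 2 and s.p_value < 0.05:
                hits += 1
        assert hits == 5

    def test_n_random_below_two_rejected(self, small_mixed_network):
        with pytest.raises(ValueError):
            mt.motif_significance(small_mixed_network, n_random=1)


class TestCallMotifs:
    @staticmethod
    def stat(code, significant):
        if significant:
            return mt.MotifStatistics(code=code, name=str(code),
                                      real_count=60, null_mean=10.0,
                                      null_sd=3.0, n_randomizations=100,
                                      p_value=0.0, p_under=1.0)
        return mt.MotifStatistics(code=code, name=str(code), real_count=10,
                                  null_mean=10.0, null_sd=3.0,
                                  n_randomizations=100, p_value=0.55,
                                  p_under=0.55)

    def test_quorum_and_exclusive_algebra(self):
        sig_in = {1: 6, 2: 6, 3: 6, 4: 6, 5: 6, 6: 6, 8: 5,
                  7: 1, 9: 1, 10: 1}
        per_network = {}
        for n in range(6):
            per_network[f"net{n}"] = [
                self.stat(code, n < times) for code, times in sig_in.items()]
        calls = mt.call_motifs(per_network, conserved={1, 2, 3, 4}, quorum=5)
        assert calls.active == {1, 2, 3, 4, 5, 6, 8}
        assert calls.exclusive == {5, 6, 8}

    def test_conserved_equals_active_gives_empty_exclusive(self):
        per_network = {"n": [self.stat(1, True)]}
        calls = mt.call_motifs(per_network, conserved={1}, quorum=1)
        assert calls.exclusive == set()

    def test_quorum_above_network_count_rejected(self):
        with pytest.raises(ValueError):
            mt.call_motifs({"n": []}, conserved=set(), quorum=2)


class TestPlantTriads:
    def test_zero_count_is_identity(self, small_mixed_network):
        out, truth = syn.plant_motifs(small_mixed_network, "Protein Clique",
                                      0, seed=0)
        assert len(out.ppi_edges) == len(small_mixed_network.ppi_edges)
        assert truth.planted_motif_count == 0

    def test_disjoint_embedding_is_additive(self):
        base = mixed(ppi=[("a", "b")])
        out, truth = syn.plant_motifs(base, "Bi-feedforward Loop", 20, seed=1)
        code = mt.CLASS_BY_NAME["Bi-feedforward Loop"].code
        assert mt.census(out)[code] >= 20
        assert truth.planted_motif_count == 20

    def test_unknown_class_rejected(self, small_mixed_network):
        with pytest.raises(KeyError):
            syn.plant_motifs(small_mixed_network, "No Such Motif", 1)


def test_motif_nodes_returns_participants(small_mixed_network):
    code = mt.CLASS_BY_NAME["Protein Clique"].code
    assert mt.motif_nodes(small_mixed_network, {code}) == {"a", "b", "c"}
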