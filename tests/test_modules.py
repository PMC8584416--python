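"""SCSNW extraction, MCL clustering, key modules, TOMs, module matching."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rhizonet import simulate as sim
from rhizonet.modules import (
    conserved_module_match,
    extract_scsnw,
    identify_toms,
    mcl_cluster,
    module_meta_graph,
    module_summary,
    select_key_modules,
)

from conftest import make_net, random_simple_net


class TestScsnw:
    def test_one_seed_endpoint_suffices(self):
        net = make_net([("a", "b"), ("b", "c")])
        sub = extract_scsnw(net, {"a"})
        assert set(sub.proteins) == {"a", "b"} and sub.edge_set() == {("a", "b")}

    def test_no_seed_edges_empty_with_warning(self):
        net = make_net([("a", "b")], nodes=["s"])
        with pytest.warns(UserWarning):
            sub = extract_scsnw(net, {"s"})
        assert sub.n_edges() == 0

    def test_empty_seed_set_rejected(self, triangle):
        with pytest.raises(ValueError):
            extract_scsnw(triangle, set())

    def test_matches_brute_force_filter(self, rng):
        for _ in range(20):
            net = random_simple_net(rng, n_max=12)
            ids = sorted(net.proteins)
            seeds = {i for i in ids if rng.random() < 0.3} or {ids[0]}
            sub = extract_scsnw(net, seeds)
            want = {e for e in net.edges if e[0] in seeds or e[1] in seeds}
            assert sub.edge_set() == want


class TestMcl:
    def test_two_cliques_split_at_bridge(self):
        left = [(f"a{i}", f"a{j}") for i in range(4) for j in range(i + 1, 4)]
        right = [(f"b{i}", f"b{j}") for i in range(4) for j in range(i + 1, 4)]
        net = make_net(left + right + [("a0", "b0")])
        part = mcl_cluster(net, inflation=2.0)
        assert len(part) == 2
        groups = {frozenset(v) for v in part.modules.values()}
        assert frozenset(f"a{i}" for i in range(4)) in groups
        assert frozenset(f"b{i}" for i in range(4)) in groups

    def test_complete_graph_single_cluster(self):
        k5 = make_net([(f"v{i}", f"v{j}") for i in range(5) for j in range(i + 1, 5)])
        part = mcl_cluster(k5)
        assert len(part) == 1

    def test_clusters_refine_components(self, rng):
        for _ in range(10):
            net = random_simple_net(rng, n_max=14, p=0.25)
            part = mcl_cluster(net)
            g = net.to_networkx(drop_self_loops=True)
            comp_of = {}
            for k, comp in enumerate(nx.connected_components(g)):
                for n in comp:
                    comp_of[n] = k
            for nodes in part.modules.values():
                assert len({comp_of[n] for n in nodes}) == 1
            covered = set().union(*part.modules.values()) if part.modules else set()
            assert covered == set(g.nodes)

    def test_deterministic(self, snf_scenario):
        p1 = mcl_cluster(snf_scenario.net)
        p2 = mcl_cluster(snf_scenario.net)
        assert p1.modules == p2.modules

    def test_planted_module_recovery(self):
        aris = []
        for seed in range(10):
            cfg = sim.SimConfig(seed=seed, n_planted_modules=3,
                                module_size_range=(6, 12), module_within_density=0.9,
                                module_between_density=0.02, n_toms=0)
            sc = sim.make_snf_scenario(cfg, n_background=0)
            part = mcl_cluster(sc.net, inflation=2.0)
            assign = part.assignment()
            nodes = sorted(sc.module_truth)
            aris.append(adjusted_rand_score(
                [sc.module_truth[n] for n in nodes], [assign[n] for n in nodes]
            ))
        assert min(aris) > 0.9


class TestSummaryAndKeys:
    def test_clique_ppi_count(self):
        net = make_net([(f"v{i}", f"v{j}") for i in range(4) for j in range(i + 1, 4)])
        part = mcl_cluster(net)
        df = module_summary(part, net, seed_set=set())
        assert df.iloc[0]["n_ppis"] == 6
        assert df.iloc[0]["n_seed_proteins"] == 0

    def test_cog_enrichment_of_uniform_module(self):
        from rhizonet.datamodel import AnnotationSet

        net = make_net(
            [(f"t{i}", f"t{j}") for i in range(5) for j in range(i + 1, 5)]
            + [(f"x{i}", f"x{i+1}") for i in range(10)]
        )
        ann = AnnotationSet(
            cog={f"t{i}": frozenset("T") for i in range(5)}
            | {f"x{i}": frozenset("ECKO"[i % 4]) for i in range(11)}
        )
        part = mcl_cluster(net)
        df = module_summary(part, net, set(), ann)
        t_mod = df[df["n_nodes"] == 5].iloc[0]
        assert "T" in t_mod["enriched_cogs"].split(",")

    def test_key_module_ranking(self):
        from rhizonet.modules import ModulePartition

        part = ModulePartition(modules={
            1: {"a", "b", "c"}, 2: {"d", "e", "f", "g"}, 3: {"h", "i"}
        })
        seeds = {"h", "i", "d"}
        assert select_key_modules(part, seeds, n_key=2) == [3, 2]


class TestToms:
    def test_planted_tom_recovered(self, snf_scenario):
        sc = snf_scenario
        truth_part = {}
        for node, m in sc.module_truth.items():
            truth_part.setdefault(m, set()).add(node)
        from rhizonet.modules import ModulePartition

        part = ModulePartition(modules=truth_part)
        toms = identify_toms(sc.net, part, sorted(truth_part), min_modules=2,
                             min_degree=1)
        for planted in sc.toms:
            assert planted in toms
            assert toms.toms[planted]["n_modules"] >= 2

    def test_single_module_node_rejected(self):
        from rhizonet.modules import ModulePartition

        net = make_net([("t", "a"), ("t", "b"), ("a", "b"), ("c", "d")])
        part = ModulePartition(modules={1: {"a", "b"}, 2: {"c", "d"}})
        toms = identify_toms(net, part, [1, 2], min_modules=2, min_degree=1)
        assert "t" not in toms

    def test_module_member_excluded_as_candidate(self):
        from rhizonet.modules import ModulePartition

        net = make_net([("a", "c"), ("a", "d"), ("c", "d")])
        part = ModulePartition(modules={1: {"a", "c"}, 2: {"d"}})
        toms = identify_toms(net, part, [1, 2], min_modules=1, min_degree=0)
        assert "a" not in toms  # member of key module 1

    def test_monotone_in_thresholds(self, snf_scenario):
        sc = snf_scenario
        from rhizonet.modules import ModulePartition

        part_map = {}
        for node, m in sc.module_truth.items():
            part_map.setdefault(m, set()).add(node)
        part = ModulePartition(modules=part_map)
        keys = sorted(part_map)
        base = set(identify_toms(sc.net, part, keys, 2, 0).toms)
        for md, mm in [(2, 1), (5, 2), (3, 3)]:
            got = set(identify_toms(sc.net, part, keys, mm, md).toms)
            if mm >= 2:
                assert got <= base

    def test_zero_planted_toms_none_found(self):
        cfg = sim.SimConfig(seed=6, n_toms=0)
        sc = sim.make_snf_scenario(cfg, n_background=0)
        from rhizonet.modules import ModulePartition

        part_map = {}
        for node, m in sc.module_truth.items():
            part_map.setdefault(m, set()).add(node)
        part = ModulePartition(modules=part_map)
        toms = identify_toms(sc.net, part, sorted(part_map))
        assert len(toms) == 0


class TestMetaGraph:
    def test_edge_weights_count_ppis(self):
        from rhizonet.modules import ModulePartition

        net = make_net([("a1", "b1"), ("a2", "b1"), ("a2", "b2"), ("a1", "a2")])
        part = ModulePartition(modules={1: {"a1", "a2"}, 2: {"b1", "b2"}})
        meta = module_meta_graph(part, identify_toms(net, part, [1, 2], 2, 99), net)
        assert meta["m1"]["m2"]["weight"] == 3
        assert meta.nodes["m1"]["size"] == 2

    def test_tom_links_to_both_modules(self):
        from rhizonet.modules import ModulePartition, TomSet

        net = make_net([("t", "a"), ("t", "b"), ("a", "a2"), ("b", "b2")])
        part = ModulePartition(modules={1: {"a", "a2"}, 2: {"b", "b2"}})
        toms = TomSet(toms={"t": {"degree": 2, "modules": [1, 2], "n_modules": 2}})
        meta = module_meta_graph(part, toms, net)
        assert set(meta.neighbors("t")) == {"m1", "m2"}

    def test_no_inter_group_edges(self):
        from rhizonet.modules import ModulePartition, TomSet

        net = make_net([("a", "a2"), ("b", "b2")])
        part = ModulePartition(modules={1: {"a", "a2"}, 2: {"b", "b2"}})
        meta = module_meta_graph(part, TomSet(), net)
        assert meta.number_of_edges() == 0


class TestConservedModuleMatch:
    def fixture_mirroring_cross_species_module(self):
        """Module with 10 edges in species A; 8 have a matching pair in B and
        2 have mapped endpoints but no B edge (the suggested additions)."""
        a_edges = [(f"a{i}", f"a{i+1}") for i in range(8)] + [("a0", "a5"), ("a2", "a7")]
        amap = {f"a{i}": f"b{i}" for i in range(9)}
        b_edges = [(f"b{i}", f"b{i+1}") for i in range(8)]
        return make_net(a_edges), make_net(b_edges), amap

    def test_matched_and_suggested_counts(self):
        ga, gb, amap = self.fixture_mirroring_cross_species_module()
        res = conserved_module_match(ga, gb, amap)
        assert res.matched_edge_count == 8
        assert len(res.suggested_edges_for_b) == 2
        assert set(res.suggested_edges_for_b) == {("b0", "b5"), ("b2", "b7")}

    def test_equals_brute_force_oracle(self, rng):
        for _ in range(20):
            ga = random_simple_net(rng, n_max=10)
            gb = random_simple_net(rng, n_max=10)
            ids_a, ids_b = sorted(ga.proteins), sorted(gb.proteins)
            amap = {a: b for a, b in zip(ids_a, rng.permutation(ids_b))
                    if rng.random() < 0.7}
            res = conserved_module_match(ga, gb, amap)
            gB = gb.to_networkx()
            want = sum(
                1 for (u, v) in ga.edges
                if u in amap and v in amap and gB.has_edge(amap[u], amap[v])
            )
            assert res.matched_edge_count == want

    def test_identity_map_identical_modules(self, triangle):
        res = conserved_module_match(triangle, triangle, {p: p for p in triangle.proteins})
        assert res.matched_edge_count == 3
        assert not res.suggested_edges_for_b and not res.suggested_edges_for_a

    def test_empty_map(self, triangle):
        res = conserved_module_match(triangle, triangle, {})
        assert res.matched_edge_count == 0
        assert not res.suggested_edges_for_b

    def test_symmetric_under_swap(self, rng):
        ga = random_simple_net(rng, n_max=8)
        gb = random_simple_net(rng, n_max=8)
        amap = {a: b for a, b in zip(sorted(ga.proteins), sorted(gb.proteins))}
        fwd = conserved_module_match(ga, gb, amap)
        rev = conserved_module_match(gb, ga, {v: k for k, v in amap.items()})
        assert fwd.matched_edge_count == rev.matched_edge_count
        assert fwd.suggested_edges_for_b == rev.suggested_edges_for_a
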