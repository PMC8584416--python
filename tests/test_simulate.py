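"""Generator determinism and planted-structure recoverability."""

import filecmp
import os

import numpy as np
import pytest

from rhizonet import io
from rhizonet import simulate as sim
from rhizonet.interolog import HomologyMap, transfer_interologs


class TestConfig:
    def test_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            sim.SimConfig(ortholog_fraction=1.5)
        with pytest.raises(ValueError):
            sim.SimConfig(coexpression_rho=1.0)
        with pytest.raises(ValueError):
            sim.SimConfig(n_target_proteins=0)


class TestDeterminism:
    def test_full_emission_byte_identical(self, tmp_path):
        cfg = sim.SimConfig(seed=17, n_target_proteins=60)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = sim.simulate_all(cfg, d1)
        m2 = sim.simulate_all(cfg, d2)
        assert m1 == m2
        for name in m1.values():
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self, tmp_path):
        n1 = sim.make_snf_scenario(sim.SimConfig(seed=1)).net.edge_set()
        n2 = sim.make_snf_scenario(sim.SimConfig(seed=2)).net.edge_set()
        assert n1 != n2


class TestProteome:
    def test_repeatable_labels(self):
        cfg = sim.SimConfig(seed=1, n_target_proteins=10)
        p1, a1 = sim.make_proteome(cfg)
        p2, a2 = sim.make_proteome(cfg)
        assert {k: v.cog_cats for k, v in p1.items()} == {
            k: v.cog_cats for k, v in p2.items()
        }
        assert a1.location == a2.location

    @pytest.mark.parametrize("frac,expect", [(0.0, 0), (1.0, None)])
    def test_unknown_location_fraction_extremes(self, frac, expect):
        cfg = sim.SimConfig(seed=3, n_target_proteins=40, unknown_location_fraction=frac)
        proteins, _ = sim.make_proteome(cfg)
        n_unknown = sum(1 for p in proteins.values() if p.location == "unknown")
        assert n_unknown == (0 if frac == 0.0 else len(proteins))

    def test_every_protein_has_go_terms(self):
        proteins, ann = sim.make_proteome(sim.SimConfig(seed=5, n_target_proteins=25))
        assert all(len(p.go_terms) >= 1 for p in proteins.values())


class TestReferenceNets:
    def test_planted_partition_modularity_beats_random_split(self):
        import networkx as nx

        cfg = sim.SimConfig(seed=8, n_target_proteins=60)
        net = sim.make_reference_interactome(
            cfg, mode="planted-partition", n_blocks=2, within_p=0.9, between_p=0.01
        )
        g = net.to_networkx()
        ids = sorted(g.nodes)
        half = len(ids) // 2
        planted = [set(ids[:half]), set(ids[half:])]
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(ids))
        random_split = [set(shuffled[:half]), set(shuffled[half:])]
        assert nx.community.modularity(g, planted) > nx.community.modularity(
            g, random_split
        )

    def test_full_density_gives_complete_graph(self):
        cfg = sim.SimConfig(seed=1, n_target_proteins=5, ppi_density=1.0)
        net = sim.make_reference_interactome(cfg)
        assert net.n_edges() == 10

    def test_incompatible_density_rejected(self):
        with pytest.raises(ValueError):
            cfg = sim.SimConfig(seed=1, n_target_proteins=5, ppi_density=1.2)
            sim.make_reference_interactome(cfg)

    def test_seed_determinism(self):
        cfg = sim.SimConfig(seed=4)
        a = sim.make_reference_interactome(cfg)
        b = sim.make_reference_interactome(cfg)
        assert a.edge_set() == b.edge_set()

    def test_scale_free_exponent_recoverable(self):
        from rhizonet.topology import fit_power_law_mle

        cfg = sim.SimConfig(seed=12, n_target_proteins=2000, ppi_density=0.002)
        net = sim.make_reference_interactome(cfg, n_nodes=2000)
        degs = np.array([net.degree(p) for p in net.proteins])
        gamma = fit_power_law_mle(degs[degs > 0], x_min=2).exponent
        # preferential attachment tails near gamma ~ 3; MLE lands in a sane band
        assert 1.5 < gamma < 3.5


class TestOrthologMap:
    def test_zero_fraction_empty_map_empty_prediction(self):
        cfg = sim.SimConfig(seed=2, ortholog_fraction=0.0, n_target_proteins=30)
        ref = sim.make_reference_interactome(cfg, n_nodes=30)
        table = sim.make_ortholog_map(cfg, [f"t{i}" for i in range(30)],
                                      sorted(ref.proteins))
        assert table.empty
        hmap = HomologyMap.from_group_table(table)
        assert transfer_interologs(ref, hmap).n_edges() == 0

    def test_full_fraction_no_inparalogs_is_bijection(self):
        cfg = sim.SimConfig(seed=2, ortholog_fraction=1.0, inparalog_fraction=0.0,
                            n_target_proteins=20)
        targets = [f"t{i}" for i in range(20)]
        refs = [f"r{i}" for i in range(25)]
        table = sim.make_ortholog_map(cfg, targets, refs)
        assert len(table) == 40  # 20 groups x 2 members
        assert set(table.loc[table["side"] == "target", "protein"]) == set(targets)
        assert table.groupby("group_id").size().eq(2).all()

    def test_planted_transfer_recovered_exactly(self):
        cfg = sim.SimConfig(seed=6, n_target_proteins=40)
        ref = sim.make_reference_interactome(cfg, n_nodes=40)
        table = sim.make_ortholog_map(cfg, [f"t{i}" for i in range(40)],
                                      sorted(ref.proteins))
        truth = sim.planted_interolog_edges(table, ref)
        pred = transfer_interologs(ref, HomologyMap.from_group_table(table))
        assert pred.edge_set() == truth


class TestExpression:
    def test_signals_positive_and_mean_pcc_near_rho(self):
        cfg = sim.SimConfig(seed=10, coexpression_rho=0.8, n_replicates=10,
                            n_planted_modules=8, module_size_range=(8, 12))
        sc = sim.make_snf_scenario(cfg, n_background=0)
        expr = sim.make_expression(cfg, sc.net, groups=sc.module_truth)
        assert (expr.signals.to_numpy() > 0).all()
        logs = np.log(expr.signals)
        pccs = [
            np.corrcoef(logs.loc[u], logs.loc[v])[0, 1]
            for (u, v) in sc.net.edges
            if u != v and sc.module_truth.get(u) == sc.module_truth.get(v)
        ]
        assert len(pccs) >= 200
        assert abs(np.mean(pccs) - 0.8) < 0.1

    def test_zero_rho_mean_pcc_near_zero(self):
        cfg = sim.SimConfig(seed=13, coexpression_rho=0.0, n_replicates=10,
                            n_planted_modules=10, module_size_range=(9, 12))
        sc = sim.make_snf_scenario(cfg, n_background=0)
        expr = sim.make_expression(cfg, sc.net, groups=sc.module_truth)
        logs = np.log(expr.signals)
        pccs = [np.corrcoef(logs.loc[u], logs.loc[v])[0, 1]
                for (u, v) in sc.net.edges if u != v]
        assert len(pccs) >= 200
        assert abs(np.mean(pccs)) < 0.1

    def test_interacting_pairs_dominate_non_pairs_at_high_rho(self):
        from scipy.stats import mannwhitneyu

        cfg = sim.SimConfig(seed=14, coexpression_rho=0.9, n_replicates=10,
                            n_planted_modules=6, module_size_range=(8, 12))
        sc = sim.make_snf_scenario(cfg, n_background=0)
        expr = sim.make_expression(cfg, sc.net, groups=sc.module_truth)
        logs = np.log(expr.signals)
        genes = sorted(sc.net.proteins)
        rng = np.random.default_rng(0)
        edge_set = sc.net.edge_set()
        pair_pcc = [np.corrcoef(logs.loc[u], logs.loc[v])[0, 1]
                    for (u, v) in edge_set if u != v]
        non = []
        while len(non) < 300:
            u, v = rng.choice(genes, size=2, replace=False)
            if (min(u, v), max(u, v)) not in edge_set and \
                    sc.module_truth.get(u) != sc.module_truth.get(v):
                non.append(np.corrcoef(logs.loc[u], logs.loc[v])[0, 1])
        assert mannwhitneyu(pair_pcc, non, alternative="greater").pvalue < 0.01

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(coexpression_rho=-1.0)


class TestSnfScenario:
    def test_ground_truth_shapes(self, snf_scenario):
        sc = snf_scenario
        assert set(sc.module_truth) <= set(sc.net.proteins)
        assert set(sc.toms) <= set(sc.net.proteins)
        assert sc.seeds <= set(sc.module_truth)
        mods = set(sc.module_truth.values())
        assert len(mods) == 3

    def test_modules_are_dense(self, snf_scenario):
        sc = snf_scenario
        by_mod = {}
        for n, m in sc.module_truth.items():
            by_mod.setdefault(m, []).append(n)
        for members in by_mod.values():
            k = len(members)
            within = sum(
                1 for (u, v) in sc.net.edges
                if u in members and v in members and u != v
            )
            assert within / (k * (k - 1) / 2) >= 0.7
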