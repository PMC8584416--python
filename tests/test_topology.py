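"""Local metrics, power-law estimators, exact/greedy MDS, enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from rhizonet.datamodel import AnnotationSet
from rhizonet.topology import (
    compare_state_metrics,
    degree_distribution,
    fit_power_law_mle,
    fit_power_law_regression,
    is_dominating,
    local_metrics,
    mds_cog_enrichment,
    minimum_dominating_set,
    sample_discrete_power_law,
)

from conftest import make_net, random_simple_net


def brute_force_mds_size(net):
    """Minimum dominating-set size by exhaustive subset search (<=15 nodes)."""
    import networkx as nx

    g = net.to_networkx(drop_self_loops=True)
    nodes = sorted(g.nodes)
    n = len(nodes)
    closed = {}
    for v in nodes:
        closed[v] = set(g.neighbors(v)) | {v}
    from itertools import combinations as combs

    for k in range(0, n + 1):
        for subset in combs(nodes, k):
            covered = set()
            for v in subset:
                covered |= closed[v]
            if len(covered) == n:
                return k
    return n


class TestLocalMetrics:
    def test_triangle(self, triangle):
        m = local_metrics(triangle)
        assert (m["clustering"] == 1.0).all()
        assert (m["closeness"] == 1.0).all()
        assert (m["betweenness"] == 0.0).all()
        assert (m["aspl"] == 1.0).all()

    def test_path_center_betweenness(self):
        m = local_metrics(make_net([("a", "b"), ("b", "c")]))
        assert m.loc["b", "betweenness"] == pytest.approx(1.0)
        assert m.loc["b", "clustering"] == 0.0
        assert m.loc["a", "closeness"] == pytest.approx(1 / 1.5)

    def test_star_hand_values(self):
        edges = [("hub", f"leaf{i}") for i in range(4)]
        m = local_metrics(make_net(edges))
        assert m.loc["hub", "closeness"] == pytest.approx(1.0)
        assert m.loc["leaf0", "aspl"] == pytest.approx((1 + 3 * 2) / 4)

    def test_self_loops_ignored(self):
        with_loop = make_net([("a", "b"), ("a", "a")])
        without = make_net([("a", "b")])
        pd.testing.assert_frame_equal(local_metrics(with_loop), local_metrics(without))

    def test_empty_network(self):
        from rhizonet.datamodel import InteractionNetwork

        assert local_metrics(InteractionNetwork()).empty


class TestPowerLaw:
    def test_exact_synthetic_counts_regression(self):
        xs = np.arange(1, 11)
        dist = pd.DataFrame({"degree": xs, "count": 100.0 * xs**-2.0})
        fit = fit_power_law_regression(dist)
        assert fit.exponent == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficient == pytest.approx(100.0)

    def test_mle_closed_form_at_constant_degrees(self):
        # all degrees equal x_min=1: gamma = 1 + 1/ln 2
        fit = fit_power_law_mle(np.ones(50), x_min=1)
        assert fit.exponent == pytest.approx(1 + 1 / np.log(2))

    def test_mle_recovers_planted_exponent(self):
        degs = sample_discrete_power_law(1.5, 10000, seed=4)
        assert fit_power_law_mle(degs).exponent == pytest.approx(1.5, abs=0.1)

    def test_estimators_agree_on_clean_histograms(self):
        """On an exact power-law histogram (>= 5000 nodes) the log-log
        regression and the discrete MLE land within 0.2 of each other."""
        for gamma in (1.2, 1.5, 2.0, 2.5):
            xs = np.arange(1, 60)
            p = xs.astype(float) ** (-gamma)
            counts = np.round(8000 * p / p.sum()).astype(int)
            keep = counts > 0
            dist = pd.DataFrame({"degree": xs[keep], "count": counts[keep]})
            reg = fit_power_law_regression(dist).exponent
            # MLE needs the sample's far tail (untruncated support); the
            # x_min-0.5 continuous approximation is least biased at x_min >= 2
            degs = sample_discrete_power_law(gamma, 10000, x_max=10**6,
                                             seed=int(gamma * 10))
            mle = fit_power_law_mle(degs, x_min=2).exponent
            assert abs(mle - reg) < 0.2

    def test_too_few_degrees_or_bad_xmin_error(self):
        with pytest.raises(ValueError):
            fit_power_law_regression(pd.DataFrame({"degree": [1, 2], "count": [5, 3]}))
        with pytest.raises(ValueError):
            fit_power_law_mle(np.array([1, 2, 3]), x_min=0)

    def test_degree_distribution_drops_self_loops_and_isolates(self):
        net = make_net([("a", "b"), ("c", "c")], nodes=["d"])
        dist = degree_distribution(net)
        assert dist["count"].sum() == 2  # only a and b


class TestMds:
    def test_star_center(self):
        net = make_net([("hub", f"l{i}") for i in range(5)])
        ds = minimum_dominating_set(net, "exact")
        assert ds.objective == 1 and ds.nodes == {"hub"} and ds.optimal

    def test_path4_and_cycle6(self):
        p4 = make_net([("a", "b"), ("b", "c"), ("c", "d")])
        assert minimum_dominating_set(p4, "exact").objective == 2
        c6 = make_net([(f"v{i}", f"v{(i+1)%6}") for i in range(6)])
        assert minimum_dominating_set(c6, "exact").objective == 2

    def test_exact_equals_brute_force(self, rng):
        for _ in range(30):
            net = random_simple_net(rng, n_max=12)
            ds = minimum_dominating_set(net, "exact")
            assert is_dominating(net, ds.nodes)
            assert ds.objective == brute_force_mds_size(net)

    def test_isolated_nodes_always_included(self):
        net = make_net([("a", "b")], nodes=["iso"])
        assert "iso" in minimum_dominating_set(net, "exact").nodes

    def test_greedy_dominates_and_bounded(self, rng):
        import networkx as nx

        for _ in range(10):
            net = random_simple_net(rng, n_max=14)
            greedy = minimum_dominating_set(net, "greedy")
            exact = minimum_dominating_set(net, "exact")
            assert is_dominating(net, greedy.nodes)
            g = net.to_networkx(drop_self_loops=True)
            delta = max(d for _, d in g.degree())
            assert greedy.objective <= exact.objective * (1 + np.log(delta + 1))


class TestEnrichment:
    def test_fisher_tail_equals_hypergeometric_sum(self):
        # 2x2 table (8,2,10,80): one-sided p = P(X >= 8), X ~ Hypergeom
        from scipy.stats import hypergeom

        net = make_net([])
        ann = AnnotationSet()
        # build a network realizing the table: 10 MDS nodes (8 in cat), 90 others
        from rhizonet.datamodel import InteractionNetwork, Protein

        net = InteractionNetwork([Protein(id=f"p{i}") for i in range(100)])
        mds = {f"p{i}" for i in range(10)}
        for i in range(8):
            ann.cog[f"p{i}"] = frozenset("E")
        for i in range(10, 20):
            ann.cog[f"p{i}"] = frozenset("E")
        df = mds_cog_enrichment(mds, net, ann)
        row = df[df["category"] == "E"].iloc[0]
        # exhaustive tail: population 100, 18 in category, draw 10
        want = sum(hypergeom.pmf(k, 100, 18, 10) for k in range(8, 11))
        assert row["pvalue"] == pytest.approx(want, rel=1e-9)
        assert row["enriched"]

    def test_uniform_category_rarely_flagged(self, rng):
        from rhizonet.datamodel import InteractionNetwork, Protein

        flags = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            net = InteractionNetwork([Protein(id=f"p{i}") for i in range(60)])
            ann = AnnotationSet()
            for i in range(60):
                if r.random() < 0.3:
                    ann.cog[f"p{i}"] = frozenset("E")
            mds = {f"p{i}" for i in r.choice(60, size=12, replace=False)}
            df = mds_cog_enrichment(mds, net, ann)
            flags.append(bool(df["enriched"].any()))
        assert np.mean(flags) <= 0.1  # alpha=0.01 per test, some slack

    def test_degenerate_full_mds(self):
        from rhizonet.datamodel import InteractionNetwork, Protein

        net = InteractionNetwork([Protein(id="a"), Protein(id="b")])
        ann = AnnotationSet(cog={"a": frozenset("E")})
        df = mds_cog_enrichment({"a", "b"}, net, ann)
        assert not df["enriched"].any()
        assert np.isnan(df["odds_ratio"]).all()


class TestStateComparison:
    def test_identical_networks_p_near_one(self, rng):
        net = random_simple_net(rng, n_max=14)
        m = local_metrics(net)
        out = compare_state_metrics(m, m)
        assert (out["pvalue"] > 0.99).all()
        assert (out["median_a"] == out["median_b"]).all()

    def test_shifted_degrees_detected(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({k: rng.normal(size=150) for k in
                          ("degree", "clustering", "closeness", "betweenness", "aspl")})
        b = a.copy()
        b["degree"] = b["degree"] + 5
        out = compare_state_metrics(a, b).set_index("metric")
        assert out.loc["degree", "pvalue"] < 0.01
        assert out.loc["degree", "median_b"] - out.loc["degree", "median_a"] == pytest.approx(5, abs=0.5)

    def test_single_node_errors(self):
        m1 = pd.DataFrame({k: [1.0] for k in
                           ("degree", "clustering", "closeness", "betweenness", "aspl")})
        with pytest.raises(ValueError):
            compare_state_metrics(m1, m1)
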