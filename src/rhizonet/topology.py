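"""Topology metrics, power-law degree-distribution fits, and minimum
dominating set (MDS) controllability with COG enrichment.

Metric conventions follow the Cytoscape "Network Analysis" plugin: closeness
is the reciprocal mean distance to reachable nodes (component-local),
betweenness is normalized by (n-1)(n-2)/2 within each component, clustering
is 0 for degree < 2, and self-loops are ignored throughout.

The degree exponent gamma is estimated two ways: least squares on the
log10-log10 degree histogram (reported with R^2), and the discrete maximum
likelihood approximation

    gamma_hat = 1 + n * [ sum_i ln( x_i / (x_min - 1/2) ) ]^(-1).

A scale-free exponent below 2 motivates a dominating-set view of network
control; the exact MDS is found by branch-and-bound equivalent to the binary
program  min sum x_v  s.t.  x_v + sum_{u in N(v)} x_u >= 1  for all v.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationSet, InteractionNetwork


@dataclass
class PowerLawFit:
    coefficient: float  # a in y = a * x^(-gamma)
    exponent: float  # gamma > 0
    r_squared: float | None  # regression mode only
    x_min: int
    n_tail: int


@dataclass
class DominatingSet:
    nodes: set[str]
    optimal: bool
    objective: int


# ---------------------------------------------------------------------------
# local metrics


def local_metrics(net: InteractionNetwork | nx.Graph) -> pd.DataFrame:
    """Per-node degree, clustering, closeness, betweenness, average shortest
    path length. Self-loops are ignored."""
    g = net.to_networkx(drop_self_loops=True) if isinstance(net, InteractionNetwork) else net
    if g.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["degree", "clustering", "closeness", "betweenness", "aspl"]
        )
    degree = dict(g.degree())
    clustering = nx.clustering(g)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness: dict[str, float] = {}
    aspl: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        normalized = sub.number_of_nodes() > 2
        betweenness.update(nx.betweenness_centrality(sub, normalized=normalized))
        for node, dists in nx.all_pairs_shortest_path_length(sub):
            others = [d for t, d in dists.items() if t != node]
            aspl[node] = float(np.mean(others)) if others else 0.0
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "aspl": [aspl[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


# ---------------------------------------------------------------------------
# degree distribution and power-law fits


def degree_distribution(net: InteractionNetwork) -> pd.DataFrame:
    """(degree, count) pairs over the self-loop-free view, degree >= 1."""
    g = net.to_networkx(drop_self_loops=True)
    degs = [d for _, d in g.degree() if d > 0]
    vals, counts = np.unique(degs, return_counts=True)
    return pd.DataFrame({"degree": vals.astype(int), "count": counts.astype(int)})


def fit_power_law_regression(dist: pd.DataFrame, x_min: int = 1) -> PowerLawFit:
    """Least squares on log10(count) vs log10(degree) for degrees >= x_min."""
    if x_min < 1:
        raise ValueError("x_min must be >= 1")
    sub = dist[(dist["degree"] >= x_min) & (dist["count"] > 0)]
    if len(sub) < 3:
        raise ValueError("regression needs >= 3 distinct degrees")
    lx = np.log10(sub["degree"].to_numpy(dtype=float))
    ly = np.log10(sub["count"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(
        coefficient=float(10**intercept),
        exponent=float(-slope),
        r_squared=r2,
        x_min=x_min,
        n_tail=int(sub["count"].sum()),
    )


def fit_power_law_mle(degrees: np.ndarray, x_min: int = 1) -> PowerLawFit:
    """Discrete-approximation MLE: gamma = 1 + n / sum(ln(x_i/(x_min-0.5)))."""
    if x_min < 1:
        raise ValueError("x_min must be >= 1")
    x = np.asarray(degrees, dtype=float)
    x = x[x >= x_min]
    if x.size == 0:
        raise ValueError("no degrees at or above x_min")
    denom = float(np.sum(np.log(x / (x_min - 0.5))))
    if denom <= 0:
        raise ValueError("degenerate degree sample for MLE")
    gamma = 1.0 + x.size / denom
    return PowerLawFit(
        coefficient=float("nan"),
        exponent=gamma,
        r_squared=None,
        x_min=x_min,
        n_tail=int(x.size),
    )


def sample_discrete_power_law(
    gamma: float, n: int, x_min: int = 1, x_max: int = 10000, seed: int = 0
) -> np.ndarray:
    """Draw n values from P(x) propto x^-gamma on {x_min..x_max}."""
    rng = np.random.default_rng(seed)
    xs = np.arange(x_min, x_max + 1)
    p = xs.astype(float) ** (-gamma)
    p /= p.sum()
    return rng.choice(xs, size=n, p=p)


# ---------------------------------------------------------------------------
# minimum dominating set


def _greedy_mds(adj: dict[str, set[str]]) -> set[str]:
    """Greedy cover: repeatedly pick the node dominating most uncovered nodes
    (lexicographic tie-break)."""
    uncovered = set(adj)
    chosen: set[str] = set()
    closed = {v: adj[v] | {v} for v in adj}
    while uncovered:
        best_v, best_gain = None, -1
        for v in sorted(adj):
            gain = len(closed[v] & uncovered)
            if gain > best_gain:
                best_v, best_gain = v, gain
        chosen.add(best_v)
        uncovered -= closed[best_v]
    return chosen


def _exact_mds(adj: dict[str, set[str]]) -> set[str]:
    """Branch-and-bound exact MDS with a greedy upper bound.

    Branches on an uncovered vertex's closed neighborhood (one of its
    dominators must be chosen); nodes are bitmask-encoded for speed.
    Deterministic: vertices and branch choices in lexicographic order.
    """
    nodes = sorted(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    closed = [0] * n
    for v in nodes:
        mask = 1 << idx[v]
        for u in adj[v]:
            mask |= 1 << idx[u]
        closed[idx[v]] = mask
    full = (1 << n) - 1
    best_set = [idx[v] for v in sorted(_greedy_mds(adj))]
    best_size = len(best_set)

    def search(covered: int, chosen: list[int]) -> None:
        nonlocal best_set, best_size
        if covered == full:
            if len(chosen) < best_size:
                best_size = len(chosen)
                best_set = list(chosen)
            return
        if len(chosen) + 1 >= best_size:
            return
        # first uncovered vertex
        rem = ~covered & full
        u = (rem & -rem).bit_length() - 1
        # one of u's closed neighbors must be in the set
        for cand in sorted(i for i in range(n) if closed[u] >> i & 1):
            chosen.append(cand)
            search(covered | closed[cand], chosen)
            chosen.pop()

    search(0, [])
    return {nodes[i] for i in best_set}


def minimum_dominating_set(
    net: InteractionNetwork | nx.Graph,
    mode: str = "exact",
    exact_node_limit: int = 60,
) -> DominatingSet:
    """Minimum dominating set of the self-loop-free graph.

    ``mode="exact"`` returns a provably minimum set (branch-and-bound);
    ``mode="greedy"`` the O(log Delta)-approximate greedy set. Exact mode
    falls back to greedy above ``exact_node_limit`` nodes. Isolated nodes
    are always members.
    """
    g = net.to_networkx(drop_self_loops=True) if isinstance(net, InteractionNetwork) else g_no_loops(net)
    adj = {str(v): {str(u) for u in g.neighbors(v)} - {str(v)} for v in g.nodes}
    if mode not in ("exact", "greedy"):
        raise ValueError("mode must be 'exact' or 'greedy'")
    use_exact = mode == "exact" and len(adj) <= exact_node_limit
    nodes = _exact_mds(adj) if use_exact else _greedy_mds(adj) if adj else set()
    return DominatingSet(nodes=nodes, optimal=use_exact, objective=len(nodes))


def g_no_loops(g: nx.Graph) -> nx.Graph:
    h = g.copy()
    h.remove_edges_from(nx.selfloop_edges(h))
    return h


def is_dominating(net: InteractionNetwork | nx.Graph, nodes: set[str]) -> bool:
    g = net.to_networkx(drop_self_loops=True) if isinstance(net, InteractionNetwork) else net
    return all(v in nodes or any(u in nodes for u in g.neighbors(v)) for v in g.nodes)


# ---------------------------------------------------------------------------
# enrichment and state comparison


def mds_cog_enrichment(
    mds: DominatingSet | set[str],
    net: InteractionNetwork,
    annotations: AnnotationSet,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-COG-category Fisher enrichment of the dominating set.

    One-sided (greater) exact test on the 2x2 table (in MDS & in category,
    in MDS & not, out & in, out & not); raw and Benjamini–Hochberg adjusted
    p-values are both reported, and the enrichment flag uses the raw p.
    """
    members = mds.nodes if isinstance(mds, DominatingSet) else set(mds)
    all_nodes = set(net.proteins)
    outside = all_nodes - members
    cats = sorted({c for pid in all_nodes for c in annotations.cog_of(pid)})
    rows = []
    for cat in cats:
        in_cat = {pid for pid in all_nodes if cat in annotations.cog_of(pid)}
        a = len(members & in_cat)
        b = len(members - in_cat)
        c = len(outside & in_cat)
        d = len(outside - in_cat)
        if not outside:  # degenerate: MDS covers every node
            rows.append(
                {"category": cat, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": float("nan"), "pvalue": 1.0, "enriched": False}
            )
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"category": cat, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": float(odds), "pvalue": float(p), "enriched": p < alpha}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = []
    return df


METRICS = ("degree", "clustering", "closeness", "betweenness", "aspl")


def compare_state_metrics(
    metrics_a: pd.DataFrame, metrics_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-metric medians and two-sided Wilcoxon rank-sum p for two node
    populations (unpaired, full node sets)."""
    rows = []
    for m in METRICS:
        xa = metrics_a[m].to_numpy(dtype=float)
        xb = metrics_b[m].to_numpy(dtype=float)
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"metric {m}: need >= 2 nodes per network")
        p = float(stats.ranksums(xa, xb).pvalue)
        rows.append(
            {"metric": m, "median_a": float(np.median(xa)),
             "median_b": float(np.median(xb)), "pvalue": p}
        )
    return pd.DataFrame(rows)
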