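"""Seed-based core-subnetwork extraction, MCL clustering, TOM hubs, and
cross-species conserved-module matching.

From a curated list of symbiosis-associated seed proteins, the core
subnetwork (SCSNW) keeps every interaction touching a seed; its first
neighbors enter too, so the SCSNW is larger than the seed list. Markov
clustering (expansion / inflation on the column-stochastic walk matrix)
partitions the SCSNW into modules; the top modules by seed content are the
"key modules". Hubs outside the key modules that tie two or more of them
together are "Tie of Modules" (TOM) nodes. A simple ortholog-guided edge
matcher compares a module between two species and suggests edges missing
from one of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationSet, InteractionNetwork, edge_key


@dataclass
class ModulePartition:
    """Disjoint node modules (id -> node set) over a network."""

    modules: dict[int, set[str]]
    converged: bool = True

    def assignment(self) -> dict[str, int]:
        return {n: mid for mid, nodes in self.modules.items() for n in nodes}

    def __len__(self) -> int:
        return len(self.modules)


@dataclass
class TomSet:
    """TOM hubs with their connectivity into key modules."""

    toms: dict[str, dict] = field(default_factory=dict)  # node -> {degree, modules}

    def __len__(self) -> int:
        return len(self.toms)

    def __contains__(self, node: str) -> bool:
        return node in self.toms


def extract_scsnw(net: InteractionNetwork, seed_set: set[str]) -> InteractionNetwork:
    """Edges with at least one endpoint in the seed set; nodes are the
    endpoints of kept edges (non-seed neighbors enter the SCSNW)."""
    if not seed_set:
        raise ValueError("seed set must be nonempty")
    keep = [e for e in net.edges if e[0] in seed_set or e[1] in seed_set]
    if not keep:
        warnings.warn("no network edge touches a seed protein; SCSNW is empty")
    return net.subnetwork_from_edges(keep)


def mcl_cluster(
    net: InteractionNetwork | nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    pruning_eps: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModulePartition:
    """Markov clustering.

    The walk matrix is the column-normalized adjacency with self-loops of
    weight 1. Each round raises the matrix to the ``expansion`` power,
    inflates entries elementwise to the ``inflation`` power with column
    renormalization, and prunes entries below ``pruning_eps``. Clusters are
    the weakly connected components of the nonzero structure of the
    attractor matrix; they always refine the graph's connected components.
    """
    g = net.to_networkx(drop_self_loops=True) if isinstance(net, InteractionNetwork) else g_simple(net)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return ModulePartition(modules={})
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    np.fill_diagonal(a, a.diagonal() + 1.0)
    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < pruning_eps] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    structure = nx.Graph()
    structure.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    structure.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = sorted(
        (sorted(c) for c in nx.connected_components(structure)),
        key=lambda c: (-len(c), nodes[c[0]]),
    )
    modules = {i + 1: {nodes[j] for j in comp} for i, comp in enumerate(comps)}
    return ModulePartition(modules=modules, converged=converged)


def g_simple(g: nx.Graph) -> nx.Graph:
    h = g.copy()
    h.remove_edges_from(nx.selfloop_edges(h))
    return h


def module_summary(
    partition: ModulePartition,
    net: InteractionNetwork,
    seed_set: set[str],
    annotations: AnnotationSet | None = None,
    enrich_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module node count, within-module PPI count, seed count, and COG
    categories enriched by a one-sided Fisher exact test against the rest of
    the network (raw p < alpha flags; BH-adjusted p also reported)."""
    all_nodes = set(net.proteins)
    rows = []
    for mid in sorted(partition.modules):
        members = partition.modules[mid]
        n_ppi = sum(
            1 for (u, v) in net.edges if u != v and u in members and v in members
        )
        enriched: list[str] = []
        adj: dict[str, float] = {}
        if annotations is not None:
            rest = all_nodes - members
            cats = sorted({c for pid in all_nodes for c in annotations.cog_of(pid)})
            raw = []
            for cat in cats:
                a = sum(1 for p in members if cat in annotations.cog_of(p))
                b = len(members) - a
                c = sum(1 for p in rest if cat in annotations.cog_of(p))
                d = len(rest) - c
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
                raw.append((cat, float(p)))
            if raw:
                padj = multipletests([p for _, p in raw], method="fdr_bh")[1]
                adj = {cat: float(pa) for (cat, _), pa in zip(raw, padj)}
                enriched = [cat for cat, p in raw if p < enrich_alpha]
        rows.append(
            {
                "module": mid,
                "n_nodes": len(members),
                "n_ppis": n_ppi,
                "n_seed_proteins": len(members & seed_set),
                "enriched_cogs": ",".join(enriched),
                "enriched_cogs_adjusted_p": ";".join(
                    f"{c}:{adj[c]:.3g}" for c in enriched
                ),
            }
        )
    return pd.DataFrame(rows)


def select_key_modules(
    partition: ModulePartition, seed_set: set[str], n_key: int = 9
) -> list[int]:
    """Key modules: ranked by seed-protein count, then size, then id."""
    ranked = sorted(
        partition.modules,
        key=lambda mid: (
            -len(partition.modules[mid] & seed_set),
            -len(partition.modules[mid]),
            mid,
        ),
    )
    return ranked[:n_key]


def identify_toms(
    net: InteractionNetwork,
    partition: ModulePartition,
    key_modules: list[int],
    min_modules: int = 2,
    min_degree: int | None = None,
) -> TomSet:
    """Tie-of-Modules hubs: nodes outside every key module, with degree at
    least ``min_degree`` (default: the network's 75th-percentile degree) and
    at least one edge into each of >= ``min_modules`` distinct key modules."""
    g = net.to_networkx(drop_self_loops=True)
    if g.number_of_nodes() == 0:
        return TomSet()
    degrees = dict(g.degree())
    if min_degree is None:
        min_degree = int(np.percentile(sorted(degrees.values()), 75))
    key_members: dict[str, int] = {}
    for mid in key_modules:
        for node in partition.modules.get(mid, ()):
            key_members[node] = mid
    toms: dict[str, dict] = {}
    for node in sorted(g.nodes):
        if node in key_members or degrees[node] < min_degree:
            continue
        touched = {key_members[nb] for nb in g.neighbors(node) if nb in key_members}
        if len(touched) >= min_modules:
            toms[node] = {
                "degree": degrees[node],
                "modules": sorted(touched),
                "n_modules": len(touched),
            }
    return TomSet(toms=toms)


def module_meta_graph(
    partition: ModulePartition,
    toms: TomSet,
    net: InteractionNetwork,
    key_modules: list[int] | None = None,
) -> nx.Graph:
    """Meta-graph over modules and TOM nodes.

    Module nodes carry ``size`` (protein count); edge weights count the PPIs
    between the two groups (a TOM is a singleton group).
    """
    mids = key_modules if key_modules is not None else sorted(partition.modules)
    group_of: dict[str, str] = {}
    meta = nx.Graph()
    for mid in mids:
        name = f"m{mid}"
        meta.add_node(name, kind="module", size=len(partition.modules[mid]))
        for node in partition.modules[mid]:
            group_of[node] = name
    for node in toms.toms:
        meta.add_node(node, kind="tom", size=1)
        group_of[node] = node
    for (u, v) in net.edges:
        gu, gv = group_of.get(u), group_of.get(v)
        if gu is None or gv is None or gu == gv:
            continue
        if meta.has_edge(gu, gv):
            meta[gu][gv]["weight"] += 1
        else:
            meta.add_edge(gu, gv, weight=1)
    return meta


@dataclass
class ModuleMatch:
    matched_edge_count: int
    unmatched_a: list[tuple[str, str]]
    unmatched_b: list[tuple[str, str]]
    suggested_edges_for_b: list[tuple[str, str]]
    suggested_edges_for_a: list[tuple[str, str]]


def conserved_module_match(
    module_a: InteractionNetwork | nx.Graph,
    module_b: InteractionNetwork | nx.Graph,
    ortholog_map: dict[str, str],
) -> ModuleMatch:
    """Ortholog-guided edge matching between one module in two species.

    An A-edge (u,v) is matched iff both endpoints map and (map(u), map(v))
    is a B-edge. Unmatched A-edges whose endpoints both map become suggested
    missing edges for B; symmetrically for B with the inverted map.
    """
    ga = module_a.to_networkx(drop_self_loops=True) if isinstance(module_a, InteractionNetwork) else module_a
    gb = module_b.to_networkx(drop_self_loops=True) if isinstance(module_b, InteractionNetwork) else module_b
    inv: dict[str, str] = {}
    for k, v in ortholog_map.items():
        inv[v] = k
    matched = 0
    unmatched_a: list[tuple[str, str]] = []
    suggest_b: list[tuple[str, str]] = []
    for u, v in ga.edges:
        mu, mv = ortholog_map.get(u), ortholog_map.get(v)
        if mu is not None and mv is not None and gb.has_edge(mu, mv):
            matched += 1
        else:
            unmatched_a.append(edge_key(u, v))
            if mu is not None and mv is not None:
                suggest_b.append(edge_key(mu, mv))
    unmatched_b: list[tuple[str, str]] = []
    suggest_a: list[tuple[str, str]] = []
    for u, v in gb.edges:
        mu, mv = inv.get(u), inv.get(v)
        if not (mu is not None and mv is not None and ga.has_edge(mu, mv)):
            unmatched_b.append(edge_key(u, v))
            if mu is not None and mv is not None:
                suggest_a.append(edge_key(mu, mv))
    return ModuleMatch(
        matched_edge_count=matched,
        unmatched_a=sorted(unmatched_a),
        unmatched_b=sorted(unmatched_b),
        suggested_edges_for_b=sorted(suggest_b),
        suggested_edges_for_a=sorted(suggest_a),
    )
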