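"""Merge prediction sources into the global interactome and summarize it."""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import networkx as nx

from .datamodel import InteractionNetwork


def merge_networks(nets: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Union of nodes and unordered edges; evidence lists concatenate.

    Order-independent on the node/edge level and idempotent on edge sets.
    """
    out = InteractionNetwork()
    for net in nets:
        for p in net.proteins.values():
            if p.id not in out.proteins:
                out.add_protein(replace(p))
        for (u, v), ev in net.edges.items():
            out.add_edge(u, v, ev)
    return out


def drop_self_loops(net: InteractionNetwork) -> tuple[InteractionNetwork, int]:
    """Remove self-interactions; the node set is unchanged."""
    out = InteractionNetwork(net.proteins.values())
    removed = 0
    for (u, v), ev in net.edges.items():
        if u == v:
            removed += 1
        else:
            out.add_edge(u, v, ev)
    return out, removed


def refine_network(net: InteractionNetwork) -> InteractionNetwork:
    """Refinement applied before controllability analysis: drop
    self-interactions, then drop nodes left without any edge."""
    no_loops, _ = drop_self_loops(net)
    linked = {p for e in no_loops.edges for p in e}
    out = InteractionNetwork(
        p for p in no_loops.proteins.values() if p.id in linked
    )
    for (u, v), ev in no_loops.edges.items():
        out.add_edge(u, v, ev)
    return out


def summarize(net: InteractionNetwork) -> dict:
    """Node/edge/component counts and per-COG node proportions.

    Proportions are per-category over annotated proteins; multi-COG proteins
    contribute to each of their categories, so proportions may exceed 1 in
    total.
    """
    g = net.to_networkx()
    n_components = nx.number_connected_components(g) if g.number_of_nodes() else 0
    annotated = [p for p in net.proteins.values() if p.cog_cats]
    counts: dict[str, int] = {}
    for p in annotated:
        for c in p.cog_cats:
            counts[c] = counts.get(c, 0) + 1
    denom = len(annotated)
    proportions = {c: counts[c] / denom for c in sorted(counts)} if denom else {}
    return {
        "n_nodes": net.n_nodes(),
        "n_edges": net.n_edges(),
        "n_self_loops": len(net.self_loops()),
        "n_components": n_components,
        "n_cog_annotated": denom,
        "cog_proportions": proportions,
    }
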