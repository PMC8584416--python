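"""Network quality assessment against degree-preserving null models.

Three reliability signals are computed over the network's edges and compared
with the same quantity over an ensemble of degree-preserving rewirings
(Maslov–Sneppen double-edge swaps, self-loops held fixed):

* functional similarity of the interacting pair's GO annotations (Wang
  best-match average),
* subcellular colocalization fractions,
* Pearson correlation of the pair's (log) transcription profiles.

Real-vs-null score distributions are compared with a one-sided Wilcoxon
rank-sum test; null edges are pooled across the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import AnnotationSet, Evidence, InteractionNetwork, edge_key
from .go import GoDag, protein_functional_similarity, wang_term_similarity
from .states import ExpressionMatrix


@dataclass
class ValidationReport:
    """Edge scores for the real network and the pooled null ensemble."""

    real_scores: np.ndarray
    null_scores: np.ndarray
    statistic: float
    pvalue: float
    n_nulls: int
    summary: dict = field(default_factory=dict)


def rewire_degree_preserving(
    net: InteractionNetwork, swaps_per_edge: int = 10, seed: int = 0
) -> InteractionNetwork:
    """Randomize by double-edge swaps, preserving every node's degree.

    Self-loops are excluded from swapping and kept as-is; proposals creating
    a self-loop or a duplicate edge are rejected, so the result stays a
    simple graph with the input's exact degree sequence. Swap-rigid graphs
    (e.g. a triangle) come back unchanged. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    loops = [e for e in net.edges if e[0] == e[1]]
    edges = [e for e in net.edges if e[0] != e[1]]
    m = len(edges)
    edge_set = set(edges)
    if m >= 2:
        target = swaps_per_edge * m
        attempts = 0
        max_attempts = 20 * target + 100
        done = 0
        while done < target and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if rng.random() < 0.5:
                new1, new2 = edge_key(a, d), edge_key(c, b)
            else:
                new1, new2 = edge_key(a, c), edge_key(b, d)
            if new1[0] == new1[1] or new2[0] == new2[1] or new1 == new2:
                continue
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[i])
            edge_set.discard(edges[j])
            edges[i], edges[j] = new1, new2
            edge_set.add(new1)
            edge_set.add(new2)
            done += 1
    out = InteractionNetwork(net.proteins.values())
    ev = Evidence(kind="experimental", origin="rewired", score=0.0)
    for (u, v) in edges:
        out.add_edge(u, v, ev)
    for (u, v) in loops:
        out.add_edge(u, v, ev)
    return out


def colocalization_assessment(
    net: InteractionNetwork, annotations: AnnotationSet | None = None
) -> dict[str, float]:
    """Fractions of edges colocalized / non-colocalized / location-unknown.

    A pair is colocalized iff both locations are known and equal; it falls
    in the unknown bucket when at least one endpoint has no location.
    """
    loc = (
        annotations.location_of
        if annotations is not None
        else lambda pid: net.proteins[pid].location
    )
    n = net.n_edges()
    if n == 0:
        return {"colocalized": 0.0, "non_colocalized": 0.0, "unknown": 0.0}
    coloc = nonco = unknown = 0
    for (u, v) in net.edges:
        lu, lv = loc(u), loc(v)
        if lu == "unknown" or lv == "unknown":
            unknown += 1
        elif lu == lv:
            coloc += 1
        else:
            nonco += 1
    return {
        "colocalized": coloc / n,
        "non_colocalized": nonco / n,
        "unknown": unknown / n,
    }


def _edge_pcc(net: InteractionNetwork, profiles: dict[str, np.ndarray]) -> np.ndarray:
    """PCC per edge, skipping self-loops and pairs lacking usable profiles."""
    out = []
    for (u, v) in net.edges:
        if u == v:
            continue
        pu, pv = profiles.get(u), profiles.get(v)
        if pu is None or pv is None:
            continue
        out.append(float(pu @ pv))
    return np.asarray(out, dtype=float)


def _standardized_profiles(expr: ExpressionMatrix) -> dict[str, np.ndarray]:
    """Per-gene standardized log-profiles (constant profiles excluded),
    scaled so that the dot product of two profiles is their PCC."""
    logs = expr.log_profiles().to_numpy(dtype=float)
    genes = expr.genes
    mean = logs.mean(axis=1, keepdims=True)
    centered = logs - mean
    norm = np.sqrt((centered**2).sum(axis=1))
    out = {}
    for i, g in enumerate(genes):
        if norm[i] > 0:
            out[g] = centered[i] / norm[i]
    return out


def coexpression_validation(
    net: InteractionNetwork,
    expression: ExpressionMatrix,
    n_nulls: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Compare per-edge transcription-profile PCC against rewired nulls.

    One-sided rank-sum test with alternative "real PCC greater than pooled
    null PCC". Requires at least 3 profile points and n_nulls >= 1.
    """
    if expression.n_replicates < 3:
        raise ValueError("coexpression validation needs >= 3 profile points")
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    profiles = _standardized_profiles(expression)
    real = _edge_pcc(net, profiles)
    pooled = []
    for k in range(n_nulls):
        null_net = rewire_degree_preserving(net, swaps_per_edge, seed=seed * 100003 + k)
        pooled.append(_edge_pcc(null_net, profiles))
    null_scores = np.concatenate(pooled) if pooled else np.empty(0)
    if real.size == 0 or null_scores.size == 0:
        raise ValueError("no scorable edges in the real or null networks")
    res = stats.mannwhitneyu(real, null_scores, alternative="greater")
    return ValidationReport(
        real_scores=real,
        null_scores=null_scores,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_nulls=n_nulls,
        summary={
            "median_real": float(np.median(real)),
            "median_null": float(np.median(null_scores)),
        },
    )


def functional_similarity_validation(
    net: InteractionNetwork,
    dag: GoDag,
    annotations: AnnotationSet,
    n_nulls: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Like coexpression validation, with the Wang best-match-average
    functional similarity as the per-edge score. Pairs where either protein
    has no usable GO annotation are excluded (not scored 0)."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")

    cache: dict[tuple[frozenset, frozenset], float | None] = {}

    def pair_score(u: str, v: str) -> float | None:
        ga, gb = annotations.go_of(u), annotations.go_of(v)
        key = (ga, gb) if (sorted(ga) <= sorted(gb)) else (gb, ga)
        if key not in cache:
            cache[key] = protein_functional_similarity(dag, ga, gb)
        return cache[key]

    def edge_scores(g: InteractionNetwork) -> np.ndarray:
        vals = []
        for (u, v) in g.edges:
            if u == v:
                continue
            s = pair_score(u, v)
            if s is not None:
                vals.append(s)
        return np.asarray(vals, dtype=float)

    real = edge_scores(net)
    pooled = []
    for k in range(n_nulls):
        null_net = rewire_degree_preserving(net, swaps_per_edge, seed=seed * 100003 + k)
        pooled.append(edge_scores(null_net))
    null_scores = np.concatenate(pooled)
    if real.size == 0 or null_scores.size == 0:
        raise ValueError("no scorable edges in the real or null networks")
    res = stats.mannwhitneyu(real, null_scores, alternative="greater")
    return ValidationReport(
        real_scores=real,
        null_scores=null_scores,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_nulls=n_nulls,
        summary={
            "median_real": float(np.median(real)),
            "median_null": float(np.median(null_scores)),
        },
    )
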