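"""Interolog transfer: predict target-species PPIs from reference interactomes.

Two target proteins are predicted to interact when their homologs in a
reference species (or a cross-species experimental corpus) interact. Homology
comes from ortholog group tables (InParanoid-style) or from a
bidirectional-best-hit fallback over a similarity table. Transfer crosses all
group members above an inparalog-score threshold; the edge confidence is the
product of the two member scores, max-aggregated over supporting reference
edges. For supplementary-database corpora, a reviewed-sequence restriction
keeps only transfers whose supporting reference pair is fully reviewed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import Evidence, InteractionNetwork, edge_key


@dataclass
class OrthologGroup:
    """One homology group linking target- and reference-side proteins."""

    reference_source: str
    members: list[tuple[str, str, float]]  # (protein id, side, inparalog score)

    def __post_init__(self) -> None:
        for pid, side, score in self.members:
            if side not in ("target", "reference"):
                raise ValueError(f"invalid side {side!r}")
            if not 0.0 < score <= 1.0:
                raise ValueError(f"inparalog score {score} outside (0,1]")

    def side(self, which: str) -> list[tuple[str, float]]:
        return [(pid, s) for pid, sd, s in self.members if sd == which]


@dataclass
class HomologyMap:
    """Ortholog groups indexed by reference-side protein id."""

    groups: list[OrthologGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_reference: dict[str, list[OrthologGroup]] = {}
        for g in self.groups:
            for pid, _ in g.side("reference"):
                self._by_reference.setdefault(pid, []).append(g)

    def targets_of(self, reference_id: str, min_score: float = 0.0) -> list[tuple[str, float]]:
        """Target homologs of a reference protein with their combined scores.

        The combined score of a target t reached via reference r is
        score(t) * score(r); multiple routes keep the maximum.
        """
        best: dict[str, float] = {}
        for g in self._by_reference.get(reference_id, []):
            r_scores = [s for pid, s in g.side("reference") if pid == reference_id]
            r_score = max((s for s in r_scores if s >= min_score), default=None)
            if r_score is None:
                continue
            for t, t_score in g.side("target"):
                sc = t_score * r_score
                if t_score >= min_score and sc > best.get(t, -1.0):
                    best[t] = sc
        return sorted(best.items())

    @classmethod
    def from_group_table(cls, df: pd.DataFrame, reference_source: str = "") -> "HomologyMap":
        """Build from an InParanoid-style table (group_id, source, side, protein, score)."""
        groups = []
        for (gid, src), sub in df.groupby(["group_id", "source"], sort=True):
            groups.append(
                OrthologGroup(
                    reference_source=reference_source or str(src),
                    members=[
                        (str(r.protein), str(r.side), float(r.score))
                        for r in sub.itertuples()
                    ],
                )
            )
        return cls(groups=groups)


def bbh_orthologs(
    similarity: pd.DataFrame,
    evalue_cutoff: float = 1e-5,
    reference_source: str = "bbh",
    target_ids: set[str] | None = None,
) -> HomologyMap:
    """Bidirectional best hits from a two-direction similarity table.

    A group {t, r} is created iff r is among t's best-bitscore subjects and t
    among r's best, with both supporting e-values <= cutoff. Ties for best are
    all kept; every BBH pair becomes its own two-member group with score 1.0.
    ``target_ids`` names the target-species side; when omitted, the query of
    the first-seen direction of each pair is taken as the target.
    """
    ok = similarity[similarity["evalue"] <= evalue_cutoff]
    best: dict[str, set[str]] = {}
    for query, sub in ok.groupby("query"):
        top = sub["bitscore"].max()
        best[query] = set(sub.loc[sub["bitscore"] == top, "subject"])
    if target_ids is None:
        queries = list(dict.fromkeys(similarity["query"]))
    else:
        queries = sorted(q for q in best if q in target_ids)
    groups = []
    seen: set[tuple[str, str]] = set()
    for t in queries:
        for r in sorted(best.get(t, ())):
            if target_ids is not None and r in target_ids:
                continue
            if t in best.get(r, ()) and (t, r) not in seen and t != r:
                seen.add((t, r))
                seen.add((r, t))
                groups.append(
                    OrthologGroup(
                        reference_source=reference_source,
                        members=[(t, "target", 1.0), (r, "reference", 1.0)],
                    )
                )
    return HomologyMap(groups=groups)


def transfer_interologs(
    reference_net: InteractionNetwork,
    homology_map: HomologyMap,
    min_inparalog_score: float = 0.0,
) -> InteractionNetwork:
    """Transfer every reference edge across the homology map.

    For a reference edge (A,B), every target pair (a,b) with a homologous to
    A and b to B is predicted, including self-loops when one target protein
    is homologous to both ends. Confidence = product of the two member
    scores; max-aggregated when several reference edges support one pair.
    """
    best: dict[tuple[str, str], Evidence] = {}
    for (ra, rb) in reference_net.edges:
        for (ta, sa) in homology_map.targets_of(ra, min_inparalog_score):
            for (tb, sb) in homology_map.targets_of(rb, min_inparalog_score):
                key = edge_key(ta, tb)
                score = sa * sb
                prev = best.get(key)
                if prev is None or score > prev.score:
                    src = homology_map._by_reference[ra][0].reference_source
                    best[key] = Evidence(
                        kind="interolog", origin=src, score=score, ref_pair=edge_key(ra, rb)
                    )
    out = InteractionNetwork()
    for (u, v), ev in sorted(best.items()):
        out.add_edge(u, v, ev)
    return out


def restrict_to_reviewed(
    predictions: InteractionNetwork,
    reviewed_id_set: set[str],
    supplementary_origins: set[str],
    require_both: bool = True,
) -> InteractionNetwork:
    """Drop supplementary-corpus transfers whose supporting reference pair is
    not reviewed (both proteins by default; either with require_both=False).
    Evidence from primary reference species is untouched; an edge survives
    while it retains any evidence."""
    out = InteractionNetwork()
    for pid, p in predictions.proteins.items():
        out.add_protein(p)
    for (u, v), ev_list in predictions.edges.items():
        kept = []
        for ev in ev_list:
            if ev.origin in supplementary_origins and ev.ref_pair is not None:
                ra, rb = ev.ref_pair
                hits = (ra in reviewed_id_set, rb in reviewed_id_set)
                ok = all(hits) if require_both else any(hits)
                if not ok:
                    continue
            kept.append(ev)
        if kept:
            out.add_edge(u, v, kept)
    return out
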