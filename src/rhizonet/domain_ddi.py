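"""Domain-based PPI prediction.

Domain hits are filtered at the strict thresholds score > 20, e-value < 1e-5,
coverage > 0.9. Domain-domain interactions come from two routes: (i) inferred
from experimental PPI corpora — the association score of a domain pair (X,Y)
is the fraction of co-carrying protein pairs in the corpus that actually
interact, kept at score > 0.5; and (ii) a structural table (3DID-style) with
its own score column, kept at score > 0. The final DDI set is

    (ppi-derived  INTERSECT  structural)
    UNION  ppi-derived with score >= 1       (i.e. all co-occurrences interact)
    UNION  structural with score > 2.

A target PPI (a,b) — self-pairs allowed — is then predicted whenever a
carries X, b carries Y and (X,Y) is in the final set.

Because the association score is a fraction in (0,1], the printed "score > 1"
cut for ppi-derived DDIs is applied as >= 1 (only perfectly-associated pairs
qualify); a ``strict_gt_one`` flag restores the literal strict inequality.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .datamodel import DDI, DomainAssignment, Evidence, InteractionNetwork, edge_key


def filter_domains(
    assignments: Iterable[DomainAssignment],
    score_min: float = 20.0,
    evalue_max: float = 1e-5,
    coverage_min: float = 0.9,
) -> list[DomainAssignment]:
    """Keep hits with score > score_min, evalue < evalue_max, coverage > coverage_min
    (all strict, as printed)."""
    return [
        a
        for a in assignments
        if a.score > score_min and a.evalue < evalue_max and a.coverage > coverage_min
    ]


def domain_map(assignments: Iterable[DomainAssignment]) -> dict[str, frozenset[str]]:
    """protein id -> set of (filtered) domains it carries."""
    m: dict[str, set[str]] = defaultdict(set)
    for a in assignments:
        m[a.protein].add(a.domain)
    return {p: frozenset(d) for p, d in m.items()}


def _ddi_key(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x <= y else (y, x)


def infer_ddis_from_ppis(
    experimental_net: InteractionNetwork,
    domains: dict[str, frozenset[str]],
    score_threshold: float = 0.5,
) -> list[DDI]:
    """Association-score DDI inference from an experimental PPI corpus.

    For each unordered domain pair (X,Y): score = (# interacting protein
    pairs where one partner carries X and the other Y) / (# all such pairs
    among corpus proteins). Self-pairs (p,p) count when p carries both X and
    Y. DDIs with score > score_threshold are returned.
    """
    proteins = sorted(domains)
    num: dict[tuple[str, str], int] = defaultdict(int)
    den: dict[tuple[str, str], int] = defaultdict(int)

    def pairs_of(p: str, q: str) -> set[tuple[str, str]]:
        dp, dq = domains[p], domains[q]
        return {_ddi_key(x, y) for x in dp for y in dq}

    for p, q in combinations(proteins, 2):
        dkeys = pairs_of(p, q)
        hit = experimental_net.has_edge(p, q)
        for k in dkeys:
            den[k] += 1
            if hit:
                num[k] += 1
    # explicit self-pairs: (p,p) is a candidate for (X,Y) only when X != Y
    # both sit on p (a homotypic (X,X) needs two distinct carriers)
    for p in proteins:
        dp = domains[p]
        dkeys = {_ddi_key(x, y) for x in dp for y in dp if x != y}
        hit = experimental_net.has_edge(p, p)
        for k in dkeys:
            den[k] += 1
            if hit:
                num[k] += 1

    out = []
    for k in sorted(den):
        score = num[k] / den[k]
        if score > score_threshold:
            out.append(DDI(domains=k, source="ppi-derived", score=score))
    return out


def combine_ddi_sets(
    ppi_ddis: Sequence[DDI],
    structural_ddis: Sequence[DDI],
    ppi_high: float = 1.0,
    structural_high: float = 2.0,
    strict_gt_one: bool = False,
) -> list[DDI]:
    """Combine the two DDI routes per the set rule in the module docstring.

    Provenance of each retained DDI is recorded in its ``source``
    ("intersection", "ppi-derived", "structural"); the score kept is the
    maximum over its supporting routes.
    """
    ppi_by_key = {d.domains: d for d in ppi_ddis}
    str_by_key = {d.domains: d for d in structural_ddis}
    out: dict[tuple[str, str], DDI] = {}
    for k in ppi_by_key.keys() & str_by_key.keys():
        out[k] = DDI(
            domains=k,
            source="intersection",
            score=max(ppi_by_key[k].score, str_by_key[k].score),
        )
    for k, d in ppi_by_key.items():
        ok = d.score > ppi_high if strict_gt_one else d.score >= ppi_high
        if ok and k not in out:
            out[k] = DDI(domains=k, source="ppi-derived", score=d.score)
    for k, d in str_by_key.items():
        if d.score > structural_high and k not in out:
            out[k] = DDI(domains=k, source="structural", score=d.score)
    return [out[k] for k in sorted(out)]


def predict_ppis_from_ddis(
    target_domains: dict[str, frozenset[str]],
    final_ddis: Sequence[DDI],
) -> InteractionNetwork:
    """Predict target PPIs from the final DDI set.

    Edge (a,b) (a=b allowed) is emitted iff some final DDI (X,Y) has X on a
    and Y on b; evidence score is the maximum supporting DDI score and origin
    the provenance of that DDI.
    """
    carriers: dict[str, list[str]] = defaultdict(list)
    for p, doms in target_domains.items():
        for d in doms:
            carriers[d].append(p)
    best: dict[tuple[str, str], DDI] = {}
    for ddi in final_ddis:
        x, y = ddi.domains
        for a in carriers.get(x, ()):
            for b in carriers.get(y, ()):
                k = edge_key(a, b)
                prev = best.get(k)
                if prev is None or ddi.score > prev.score:
                    best[k] = ddi
    net = InteractionNetwork()
    for (a, b), ddi in sorted(best.items()):
        net.add_edge(a, b, Evidence(kind="ddi", origin=ddi.source, score=ddi.score))
    return net
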