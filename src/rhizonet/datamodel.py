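"""Core data model: proteins, evidence-tagged interaction networks, annotations.

The interactome is an undirected graph whose edges are unordered protein-id
pairs, each carrying one or more evidence records (interolog transfer,
domain-domain inference, or experimental observation). Self-interactions are
representable and flagged; downstream steps that must ignore them (topology
metrics, dominating sets) do so explicitly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import networkx as nx

COG_ALPHABET = frozenset(string.ascii_uppercase)

LOCATIONS = frozenset(
    {
        "cytoplasmic",
        "inner-membrane",
        "periplasmic",
        "outer-membrane",
        "extracellular",
        "unknown",
    }
)

EVIDENCE_KINDS = frozenset({"interolog", "ddi", "experimental"})


@dataclass
class Protein:
    """A node of the interactome.

    ``id`` is an opaque, case-sensitive locus tag or accession. ``cog_cats``
    may hold zero, one or several single-letter COG categories (multi-COG
    assignment is common and is honoured by every counting step).
    """

    id: str
    description: str = ""
    cog_cats: frozenset[str] = frozenset()
    go_terms: frozenset[str] = frozenset()
    location: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        self.cog_cats = frozenset(self.cog_cats)
        self.go_terms = frozenset(self.go_terms)
        bad = self.cog_cats - COG_ALPHABET
        if bad:
            raise ValueError(f"invalid COG letters {sorted(bad)} for protein {self.id}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r} for protein {self.id}")


@dataclass(frozen=True)
class Evidence:
    """Provenance of one edge: how it was predicted/observed and how strongly.

    ``ref_pair`` optionally records the supporting reference-protein pair for
    interolog transfers (needed for the reviewed-sequence restriction applied
    to supplementary-database corpora).
    """

    kind: str
    origin: str = ""
    score: float = 1.0
    ref_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVIDENCE_KINDS:
            raise ValueError(f"evidence kind must be one of {sorted(EVIDENCE_KINDS)}")
        if self.score < 0:
            raise ValueError("evidence score must be nonnegative")


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered edge identity (sorted id pair)."""
    return (u, v) if u <= v else (v, u)


class InteractionNetwork:
    """Undirected PPI network with per-edge evidence lists.

    Edge identity is the unordered id pair; duplicate submissions merge their
    evidence. Self-loops are allowed, stored once, and reported by
    :meth:`self_loops`.
    """

    def __init__(self, proteins: Iterable[Protein] = ()) -> None:
        self.proteins: dict[str, Protein] = {}
        self._edges: dict[tuple[str, str], list[Evidence]] = {}
        for p in proteins:
            self.add_protein(p)

    # -- construction -------------------------------------------------------

    def add_protein(self, protein: Protein) -> None:
        self.proteins[protein.id] = protein

    def ensure_protein(self, pid: str) -> Protein:
        if pid not in self.proteins:
            self.proteins[pid] = Protein(id=pid)
        return self.proteins[pid]

    def add_edge(self, u: str, v: str, evidence: Evidence | Iterable[Evidence]) -> None:
        ev = [evidence] if isinstance(evidence, Evidence) else list(evidence)
        if not ev:
            raise ValueError("edge requires at least one evidence record")
        self.ensure_protein(u)
        self.ensure_protein(v)
        self._edges.setdefault(edge_key(u, v), []).extend(ev)

    # -- queries ------------------------------------------------------------

    @property
    def edges(self) -> Mapping[tuple[str, str], list[Evidence]]:
        return self._edges

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def has_edge(self, u: str, v: str) -> bool:
        return edge_key(u, v) in self._edges

    def evidence(self, u: str, v: str) -> list[Evidence]:
        return self._edges[edge_key(u, v)]

    def self_loops(self) -> list[tuple[str, str]]:
        return [e for e in self._edges if e[0] == e[1]]

    def n_nodes(self) -> int:
        return len(self.proteins)

    def n_edges(self) -> int:
        return len(self._edges)

    def degree(self, pid: str) -> int:
        """Number of incident edges; a self-loop contributes 1."""
        return sum(1 for e in self._edges if pid in e)

    def neighbors(self, pid: str) -> set[str]:
        out: set[str] = set()
        for (u, v) in self._edges:
            if u == pid:
                out.add(v)
            elif v == pid:
                out.add(u)
        return out

    def __iter__(self) -> Iterator[str]:
        return iter(self.proteins)

    def __contains__(self, pid: str) -> bool:
        return pid in self.proteins

    # -- derived views ------------------------------------------------------

    def to_networkx(self, drop_self_loops: bool = False) -> nx.Graph:
        """Simple-graph view; evidence lists attach to edges as ``evidence``."""
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        for (u, v), ev in self._edges.items():
            if drop_self_loops and u == v:
                continue
            g.add_edge(u, v, evidence=list(ev))
        return g

    def copy(self) -> "InteractionNetwork":
        out = InteractionNetwork()
        for p in self.proteins.values():
            out.add_protein(replace(p))
        for (u, v), ev in self._edges.items():
            out._edges[(u, v)] = list(ev)
        return out

    def subnetwork_from_edges(
        self, keep: Iterable[tuple[str, str]]
    ) -> "InteractionNetwork":
        """Network induced by the given edges; nodes = their endpoints."""
        out = InteractionNetwork()
        for e in keep:
            k = edge_key(*e)
            ev = self._edges[k]
            for pid in set(k):
                out.add_protein(replace(self.proteins[pid]))
            out._edges[k] = list(ev)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork(nodes={self.n_nodes()}, edges={self.n_edges()})"


@dataclass(frozen=True)
class DomainAssignment:
    """One Pfam-style domain hit on a protein."""

    protein: str
    domain: str
    score: float
    evalue: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(
                f"coverage {self.coverage} outside [0,1] for {self.protein}/{self.domain}"
            )
        if self.evalue < 0:
            raise ValueError("e-value must be nonnegative")


@dataclass(frozen=True)
class DDI:
    """A scored, unordered domain-domain interaction."""

    domains: tuple[str, str]
    source: str  # "ppi-derived" | "structural" | combined provenance label
    score: float

    def __post_init__(self) -> None:
        a, b = self.domains
        object.__setattr__(self, "domains", (a, b) if a <= b else (b, a))


@dataclass
class AnnotationSet:
    """Per-protein GO / COG / subcellular-location labels."""

    go: dict[str, frozenset[str]] = field(default_factory=dict)
    cog: dict[str, frozenset[str]] = field(default_factory=dict)
    location: dict[str, str] = field(default_factory=dict)

    def cog_of(self, pid: str) -> frozenset[str]:
        return self.cog.get(pid, frozenset())

    def go_of(self, pid: str) -> frozenset[str]:
        return self.go.get(pid, frozenset())

    def location_of(self, pid: str) -> str:
        return self.location.get(pid, "unknown")

    def apply(self, net: InteractionNetwork) -> None:
        """Copy labels onto matching network proteins in place."""
        for pid, p in net.proteins.items():
            net.proteins[pid] = replace(
                p,
                cog_cats=self.cog.get(pid, p.cog_cats),
                go_terms=self.go.get(pid, p.go_terms),
                location=self.location.get(pid, p.location),
            )
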