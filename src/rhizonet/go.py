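"""Gene Ontology DAG and Wang semantic similarity.

The Wang measure scores two GO terms by the overlap of their ancestor sets,
weighting each ancestor by a semantic contribution that decays multiplicatively
along ``is_a`` (w=0.8) and ``part_of`` (w=0.6) edges — the constants of the
G-SESAME algorithm. Protein-level similarity is the best-match average of the
term-level scores, computed within each GO namespace and averaged over the
namespaces where both proteins are annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class GoDag:
    """Typed term DAG with child->parent edges and contribution weights."""

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    _parents: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    _namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.weights.values():
            if not 0.0 < w < 1.0:
                raise ValueError("semantic contribution weights must lie in (0,1)")

    def add_term(self, term: str, namespace: str = "biological_process") -> None:
        self._parents.setdefault(term, [])
        self._namespace[term] = namespace

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        if relation not in self.weights:
            raise ValueError(f"unknown relation {relation!r}")
        self.add_term(child, self._namespace.get(child, "biological_process"))
        self.add_term(parent, self._namespace.get(parent, "biological_process"))
        self._parents[child].append((parent, relation))

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def terms(self) -> list[str]:
        return list(self._parents)

    def parents(self, term: str) -> list[tuple[str, str]]:
        return self._parents[term]

    def namespace(self, term: str) -> str:
        return self._namespace.get(term, "biological_process")

    def edges(self) -> list[tuple[str, str, str]]:
        return [(c, p, r) for c, ps in self._parents.items() for p, r in ps]

    def validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        g.add_edges_from((c, p) for c, p, _ in self.edges())
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO relation graph contains a cycle; a DAG is required")

    # -- Wang measure -------------------------------------------------------

    def s_values(self, term: str) -> dict[str, float]:
        """Semantic contribution of every ancestor of ``term`` (incl. itself).

        S_A(A)=1; walking up, each edge multiplies by its relation weight and
        an ancestor reachable by several paths keeps the maximum.
        """
        if term not in self._parents:
            raise KeyError(f"term {term!r} not in DAG")
        s: dict[str, float] = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt: list[str] = []
            for t in frontier:
                for parent, rel in self._parents[t]:
                    cand = s[t] * self.weights[rel]
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        return s


def wang_term_similarity(dag: GoDag, term_a: str, term_b: str) -> float:
    """Wang semantic similarity of two GO terms, in [0,1]."""
    sa = dag.s_values(term_a)
    sb = dag.s_values(term_b)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    num = sum(sa[t] + sb[t] for t in common)
    return num / (sum(sa.values()) + sum(sb.values()))


def protein_functional_similarity(
    dag: GoDag, go_set_a: frozenset[str] | set[str], go_set_b: frozenset[str] | set[str]
) -> float | None:
    """Best-match-average similarity of two GO annotation sets.

    Computed per namespace and averaged over the namespaces where both
    proteins carry terms. Returns None when no namespace is shared (the pair
    is then excluded from validation distributions rather than scored 0).
    """
    terms_a = [t for t in go_set_a if t in dag]
    terms_b = [t for t in go_set_b if t in dag]
    if not terms_a or not terms_b:
        return None
    by_ns_a: dict[str, list[str]] = {}
    by_ns_b: dict[str, list[str]] = {}
    for t in terms_a:
        by_ns_a.setdefault(dag.namespace(t), []).append(t)
    for t in terms_b:
        by_ns_b.setdefault(dag.namespace(t), []).append(t)
    shared = sorted(by_ns_a.keys() & by_ns_b.keys())
    if not shared:
        return None
    sims = []
    for ns in shared:
        aa, bb = by_ns_a[ns], by_ns_b[ns]
        cache = {
            (x, y): wang_term_similarity(dag, x, y) for x in aa for y in bb
        }
        best_a = sum(max(cache[(x, y)] for y in bb) for x in aa)
        best_b = sum(max(cache[(x, y)] for x in aa) for y in bb)
        sims.append((best_a + best_b) / (len(aa) + len(bb)))
    return sum(sims) / len(sims)
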