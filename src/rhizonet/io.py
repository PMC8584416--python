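"""Readers and writers for the pipeline's external formats.

Formats: plain TSV edge lists, SIF, GraphML (via networkx), HMMER domtblout
(or a simplified 5-column domain TSV), OBO 1.2 (via obonet), a GAF-like
annotation TSV, expression TSV with paired signal/p-value columns, 3DID-style
DDI tables, InParanoid-style ortholog group tables and BLAST-tabular
similarity tables.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet
import pandas as pd

from .datamodel import (
    AnnotationSet,
    DDI,
    DomainAssignment,
    Evidence,
    InteractionNetwork,
    Protein,
)
from .go import GoDag
from .states import ExpressionMatrix


class FormatError(ValueError):
    """Raised for malformed input files; the message names the line."""


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path: str | Path,
    id_cols: tuple[int, int] = (0, 1),
    score_col: int | None = None,
    source_col: int | None = None,
    kind: str = "experimental",
) -> InteractionNetwork:
    """Read a whitespace/tab-delimited edge list.

    Duplicate unordered pairs merge with concatenated evidence; a
    single-token line denotes an isolated node. Lines starting with '#' are
    comments.
    """
    net = InteractionNetwork()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 1:
                net.ensure_protein(parts[0])
                continue
            needed = max(
                id_cols[0], id_cols[1], score_col or 0, source_col or 0
            )
            if len(parts) <= needed:
                raise FormatError(f"{path}: line {lineno}: expected >{needed} columns")
            u, v = parts[id_cols[0]], parts[id_cols[1]]
            score = 1.0
            if score_col is not None:
                try:
                    score = float(parts[score_col])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score {parts[score_col]!r}"
                    ) from exc
            origin = parts[source_col] if source_col is not None else ""
            net.add_edge(u, v, Evidence(kind=kind, origin=origin, score=score))
    return net


def _evidence_str(ev_list: list[Evidence]) -> str:
    return ";".join(f"{e.kind}:{e.origin}:{e.score:g}" for e in ev_list)


def _parse_evidence_str(s: str) -> list[Evidence]:
    out = []
    for chunk in s.split(";"):
        if not chunk:
            continue
        kind, origin, score = chunk.split(":")
        out.append(Evidence(kind=kind, origin=origin, score=float(score)))
    return out or [Evidence(kind="experimental")]


def write_network(net: InteractionNetwork, path: str | Path, format: str = "tsv") -> None:
    """Export as SIF, GraphML, or TSV; round-trips node and edge sets."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# source\ttarget\tevidence\n")
            linked = {p for e in net.edges for p in e}
            for (u, v), ev in sorted(net.edges.items()):
                fh.write(f"{u}\t{v}\t{_evidence_str(ev)}\n")
            for pid in sorted(set(net.proteins) - linked):
                fh.write(f"{pid}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            linked = {p for e in net.edges for p in e}
            for (u, v) in sorted(net.edges):
                fh.write(f"{u}\tpp\t{v}\n")
            for pid in sorted(set(net.proteins) - linked):
                fh.write(f"{pid}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(sorted(net.proteins))
        for (u, v), ev in sorted(net.edges.items()):
            g.add_edge(u, v, evidence=_evidence_str(ev))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "tsv") -> InteractionNetwork:
    """Inverse of :func:`write_network`."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        net = InteractionNetwork()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    net.ensure_protein(parts[0].strip())
                elif len(parts) >= 2:
                    ev = (
                        _parse_evidence_str(parts[2])
                        if len(parts) >= 3
                        else [Evidence(kind="experimental")]
                    )
                    net.add_edge(parts[0], parts[1], ev)
                else:
                    raise FormatError(f"{path}: line {lineno}: malformed")
        return net
    if fmt == "sif":
        net = InteractionNetwork()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                parts = raw.split()
                if not parts:
                    continue
                if len(parts) == 1:
                    net.ensure_protein(parts[0])
                elif len(parts) == 3:
                    net.add_edge(parts[0], parts[2], Evidence(kind="experimental"))
                else:
                    raise FormatError(f"{path}: line {lineno}: SIF expects 1 or 3 columns")
        return net
    if fmt == "graphml":
        g = nx.read_graphml(path)
        net = InteractionNetwork()
        for n in g.nodes:
            net.ensure_protein(str(n))
        for u, v, data in g.edges(data=True):
            net.add_edge(str(u), str(v), _parse_evidence_str(data.get("evidence", "")))
        return net
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# domain tables


def read_domain_table(path: str | Path) -> list[DomainAssignment]:
    """Read domain hits from HMMER domtblout or a simplified 5-column TSV.

    domtblout rows (>=23 whitespace-delimited fields) are interpreted with
    the protein as the query and the domain model as the target; coverage is
    model coverage, (hmm_to - hmm_from + 1) / model_length.
    Simplified rows: protein, domain, score, evalue, coverage.
    """
    out: list[DomainAssignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) >= 23:  # HMMER domtblout
                    domain, protein = parts[0], parts[3]
                    model_len = int(parts[2])
                    score = float(parts[13])  # per-domain bit score
                    evalue = float(parts[12])  # i-Evalue
                    hmm_from, hmm_to = int(parts[15]), int(parts[16])
                    coverage = (hmm_to - hmm_from + 1) / model_len
                elif len(parts) == 5:
                    protein, domain = parts[0], parts[1]
                    score, evalue, coverage = (
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                    )
                else:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 5 or >=23 columns, got {len(parts)}"
                    )
                out.append(
                    DomainAssignment(
                        protein=protein,
                        domain=domain,
                        score=score,
                        evalue=evalue,
                        coverage=coverage,
                    )
                )
            except (ValueError, ZeroDivisionError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_domain_table(assignments: Iterable[DomainAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tdomain\tscore\tevalue\tcoverage\n")
        for a in assignments:
            fh.write(f"{a.protein}\t{a.domain}\t{a.score:g}\t{a.evalue:g}\t{a.coverage:g}\n")


# ---------------------------------------------------------------------------
# DDI tables (3DID-style)


def read_ddi_table(path: str | Path, source: str = "structural") -> list[DDI]:
    """Read a 3DID-style table: domainA, domainB, score."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric score") from exc
            out.append(DDI(domains=(parts[0], parts[1]), source=source, score=score))
    return out


def write_ddi_table(ddis: Iterable[DDI], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# domainA\tdomainB\tscore\n")
        for d in sorted(ddis, key=lambda d: d.domains):
            fh.write(f"{d.domains[0]}\t{d.domains[1]}\t{d.score:g}\n")


# ---------------------------------------------------------------------------
# GO DAG and annotations


def read_obo(path: str | Path, weights: dict[str, float] | None = None) -> GoDag:
    """Parse an OBO 1.2 ontology into a :class:`GoDag` (is_a and part_of)."""
    graph = obonet.read_obo(path)
    dag = GoDag(weights=dict(weights)) if weights else GoDag()
    for term, data in graph.nodes(data=True):
        dag.add_term(term, data.get("namespace", "biological_process"))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent, "is_a")
        elif key == "part_of":
            dag.add_edge(child, parent, "part_of")
    dag.validate_acyclic()
    return dag


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Minimal OBO 1.2 writer (term stanzas with is_a / part_of relations)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {dag.namespace(term)}\n")
            for parent, rel in sorted(dag.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GAF-like TSV: protein, go_terms, cog_cats, location.

    GO terms and COG letters are comma-concatenated; '-' or empty means
    unannotated. Missing trailing columns are tolerated.
    """
    ann = AnnotationSet()
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            pid = parts[0]
            if len(parts) > 1 and parts[1] not in ("", "-"):
                ann.go[pid] = frozenset(parts[1].split(","))
            if len(parts) > 2 and parts[2] not in ("", "-"):
                ann.cog[pid] = frozenset(parts[2].replace(",", ""))
            if len(parts) > 3 and parts[3] not in ("", "-"):
                ann.location[pid] = parts[3]
    return ann


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    pids = sorted(set(ann.go) | set(ann.cog) | set(ann.location))
    with open(path, "w") as fh:
        fh.write("# protein\tgo_terms\tcog_cats\tlocation\n")
        for pid in pids:
            go = ",".join(sorted(ann.go.get(pid, ()))) or "-"
            cog = ",".join(sorted(ann.cog.get(pid, ()))) or "-"
            loc = ann.location.get(pid, "unknown")
            fh.write(f"{pid}\t{go}\t{cog}\t{loc}\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, state: str = "") -> ExpressionMatrix:
    """Read an expression TSV with paired columns rep<i>_signal, rep<i>_p."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    sig_cols = [c for c in df.columns if c.endswith("_signal")]
    p_cols = [c for c in df.columns if c.endswith("_p")]
    if len(sig_cols) != len(p_cols) or not sig_cols:
        raise FormatError(f"{path}: expected paired *_signal/*_p columns")
    signals = df[sig_cols].copy()
    signals.columns = [c[: -len("_signal")] for c in sig_cols]
    pvalues = df[p_cols].copy()
    pvalues.columns = [c[: -len("_p")] for c in p_cols]
    pvalues = pvalues[signals.columns]
    return ExpressionMatrix(signals=signals, pvalues=pvalues, state=state)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = {}
    for c in expr.signals.columns:
        out[f"{c}_signal"] = expr.signals[c]
        out[f"{c}_p"] = expr.pvalues[c]
    pd.DataFrame(out, index=expr.signals.index).to_csv(
        path, sep="\t", index_label="gene", float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# ortholog groups / similarity tables / seed lists


def read_ortholog_groups(path: str | Path) -> pd.DataFrame:
    """InParanoid-style group TSV: group_id, source, side, protein, score."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["group_id", "source", "side", "protein", "score"],
        dtype={"group_id": int, "score": float},
    )
    bad = ~df["side"].isin(["target", "reference"])
    if bad.any():
        raise FormatError(f"{path}: invalid side values {df['side'][bad].unique()}")
    return df


def write_ortholog_groups(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, quoting=csv.QUOTE_NONE)


def read_similarity_table(path: str | Path) -> pd.DataFrame:
    """BLAST-tabular-like TSV: query, subject, bitscore, evalue."""
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["query", "subject", "bitscore", "evalue"],
        dtype={"bitscore": float, "evalue": float},
    )


def read_seed_list(path: str | Path) -> set[str]:
    """One protein id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_seed_list(seeds: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(seeds):
            fh.write(f"{s}\n")
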