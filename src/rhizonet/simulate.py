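"""Synthetic inputs with planted, recoverable structure.

Every file the pipeline consumes — reference interactomes, ortholog group
tables, domain assignments, structural DDI tables, a GO DAG with
annotations, expression matrices with per-replicate detection p-values, and
a seed list with planted modules and Tie-of-Modules hubs — can be generated
here, together with the ground truth needed to test recovery. All
generators are deterministic under the configured seed.

The defaults emulate the shape of the real study inputs: ~92% of proteins
COG-annotated with 'E' the largest category, a quarter of proteins without
subcellular location, 15 expression replicates with a 0.06 detection
p-value boundary, and dense (>=0.7 within-density) symbiosis modules around
seed proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationSet,
    DDI,
    DomainAssignment,
    Evidence,
    InteractionNetwork,
    Protein,
    edge_key,
)
from .go import GoDag

# categorical COG weights (normalized at draw time); 'E' largest, 'D' rare
COG_WEIGHTS = {
    "E": 0.120, "R": 0.100, "S": 0.090, "K": 0.080, "G": 0.070, "C": 0.070,
    "M": 0.060, "P": 0.060, "T": 0.060, "J": 0.050, "O": 0.040, "H": 0.040,
    "I": 0.040, "L": 0.040, "F": 0.030, "Q": 0.030, "N": 0.020, "U": 0.020,
    "V": 0.020, "D": 0.005,
}

KNOWN_LOCATIONS = (
    "cytoplasmic",
    "inner-membrane",
    "periplasmic",
    "outer-membrane",
    "extracellular",
)


@dataclass
class SimConfig:
    """Study conditions for all generators."""

    seed: int = 0
    n_target_proteins: int = 300
    n_reference_species: int = 2
    ortholog_fraction: float = 0.6
    inparalog_fraction: float = 0.1
    ppi_density: float = 0.02
    n_planted_modules: int = 3
    module_size_range: tuple[int, int] = (6, 12)
    module_within_density: float = 0.9
    module_between_density: float = 0.02
    n_toms: int = 2
    coexpression_rho: float = 0.8
    n_replicates: int = 15
    detection_rate: float = 0.9
    annotated_fraction: float = 0.92
    multi_cog_fraction: float = 0.15
    unknown_location_fraction: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "ortholog_fraction", "inparalog_fraction", "detection_rate",
            "annotated_fraction", "multi_cog_fraction", "unknown_location_fraction",
            "module_within_density", "module_between_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not -1.0 < self.coexpression_rho < 1.0:
            raise ValueError("coexpression_rho must lie in (-1,1)")
        if self.n_target_proteins <= 0 or self.n_replicates <= 0:
            raise ValueError("sizes must be positive")

    def rng(self, stream) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        key = tuple(stream) if isinstance(stream, tuple) else (stream,)
        return np.random.default_rng((self.seed,) + key)


# ---------------------------------------------------------------------------
# GO DAG and proteome


def make_go_dag(cfg: SimConfig, n_terms: int = 60) -> GoDag:
    """Random DAG: one root per namespace, each new term gets 1-2 parents."""
    rng = cfg.rng(1)
    dag = GoDag()
    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    per_ns = max(2, n_terms // len(namespaces))
    for k, ns in enumerate(namespaces):
        terms = [f"GO:{k:02d}{i:05d}" for i in range(per_ns)]
        dag.add_term(terms[0], ns)
        for i, t in enumerate(terms[1:], start=1):
            dag.add_term(t, ns)
            n_parents = 1 if i == 1 else int(rng.integers(1, 3))
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in np.atleast_1d(parents):
                rel = "is_a" if rng.random() < 0.8 else "part_of"
                dag.add_edge(t, terms[int(p)], rel)
    dag.validate_acyclic()
    return dag


def make_proteome(
    cfg: SimConfig, dag: GoDag | None = None
) -> tuple[dict[str, Protein], AnnotationSet]:
    """Target proteome with COG, GO and location labels."""
    rng = cfg.rng(2)
    dag = dag or make_go_dag(cfg)
    letters = list(COG_WEIGHTS)
    w = np.array([COG_WEIGHTS[c] for c in letters])
    w = w / w.sum()
    terms = sorted(dag.terms)
    proteins: dict[str, Protein] = {}
    ann = AnnotationSet()
    for i in range(cfg.n_target_proteins):
        pid = f"bll{i:04d}"
        cogs: frozenset[str] = frozenset()
        if rng.random() < cfg.annotated_fraction:
            chosen = {str(rng.choice(letters, p=w))}
            if rng.random() < cfg.multi_cog_fraction:
                chosen.add(str(rng.choice(letters, p=w)))
            cogs = frozenset(chosen)
        n_go = int(rng.integers(1, 5))
        gos = frozenset(str(t) for t in rng.choice(terms, size=n_go, replace=False))
        if rng.random() < cfg.unknown_location_fraction:
            loc = "unknown"
        else:
            loc = str(rng.choice(KNOWN_LOCATIONS, p=[0.55, 0.2, 0.12, 0.08, 0.05]))
        proteins[pid] = Protein(
            id=pid, description=f"synthetic protein {i}", cog_cats=cogs,
            go_terms=gos, location=loc,
        )
        if cogs:
            ann.cog[pid] = cogs
        ann.go[pid] = gos
        if loc != "unknown":
            ann.location[pid] = loc
    return proteins, ann


# ---------------------------------------------------------------------------
# reference interactomes


def make_reference_interactome(
    cfg: SimConfig,
    species: str = "ref1",
    mode: str = "preferential-attachment",
    n_nodes: int | None = None,
    n_blocks: int = 2,
    within_p: float = 0.9,
    between_p: float = 0.01,
    stream: int = 3,
) -> InteractionNetwork:
    """Reference-species PPI network.

    ``preferential-attachment`` gives a scale-free graph whose degree
    exponent is recoverable by the MLE; ``planted-partition`` gives a
    modular graph. Node ids are prefixed with the species label.
    """
    rng = cfg.rng(stream)
    n = n_nodes or cfg.n_target_proteins
    if mode == "preferential-attachment":
        max_edges = n * (n - 1) // 2
        want = cfg.ppi_density * max_edges
        if cfg.ppi_density > 1:
            raise ValueError("density incompatible with n (exceeds complete graph)")
        if cfg.ppi_density == 1:
            g = nx.complete_graph(n)
        else:
            m = max(1, int(round(want / n)))
            if m >= n:
                raise ValueError("density incompatible with n for preferential attachment")
            g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    elif mode == "planted-partition":
        g = nx.planted_partition_graph(
            n_blocks, max(2, n // n_blocks), within_p, between_p,
            seed=int(rng.integers(2**31)),
        )
    else:
        raise ValueError(f"unknown generator mode {mode!r}")
    net = InteractionNetwork()
    ev = Evidence(kind="experimental", origin=species, score=1.0)
    for node in g.nodes:
        net.ensure_protein(f"{species}_{node:04d}")
    for u, v in g.edges:
        net.add_edge(f"{species}_{u:04d}", f"{species}_{v:04d}", ev)
    return net


# ---------------------------------------------------------------------------
# ortholog maps and planted interologs


def make_ortholog_map(
    cfg: SimConfig,
    target_ids: list[str],
    reference_ids: list[str],
    species: str = "ref1",
    stream: int = 4,
) -> pd.DataFrame:
    """InParanoid-style group table (group_id, source, side, protein, score).

    An ``ortholog_fraction`` of target proteins get exactly one seed
    ortholog (score 1.0) among distinct reference proteins; an
    ``inparalog_fraction`` of those groups gain an extra target inparalog
    with score in (0,1).
    """
    rng = cfg.rng(stream)
    targets = list(target_ids)
    refs = list(reference_ids)
    n_pairs = min(int(round(cfg.ortholog_fraction * len(targets))), len(refs))
    chosen_t = [targets[i] for i in rng.choice(len(targets), size=n_pairs, replace=False)]
    chosen_r = [refs[i] for i in rng.choice(len(refs), size=n_pairs, replace=False)]
    unused = sorted(set(targets) - set(chosen_t))
    rows = []
    gid = 0
    for t, r in zip(chosen_t, chosen_r):
        gid += 1
        rows.append((gid, species, "target", t, 1.0))
        rows.append((gid, species, "reference", r, 1.0))
        if unused and rng.random() < cfg.inparalog_fraction:
            extra = unused.pop(int(rng.integers(len(unused))))
            rows.append((gid, species, "target", extra, float(round(rng.uniform(0.3, 0.99), 3))))
    return pd.DataFrame(
        rows, columns=["group_id", "source", "side", "protein", "score"]
    )


def planted_interolog_edges(
    group_table: pd.DataFrame, reference_net: InteractionNetwork
) -> set[tuple[str, str]]:
    """Ground-truth transferable edges, by direct nested-loop enumeration
    (independent of the interolog module)."""
    ref_to_targets: dict[str, set[str]] = {}
    for gid, sub in group_table.groupby("group_id"):
        t_ids = sub.loc[sub["side"] == "target", "protein"].tolist()
        r_ids = sub.loc[sub["side"] == "reference", "protein"].tolist()
        for r in r_ids:
            ref_to_targets.setdefault(r, set()).update(t_ids)
    truth: set[tuple[str, str]] = set()
    for (ra, rb) in reference_net.edges:
        for a in ref_to_targets.get(ra, ()):
            for b in ref_to_targets.get(rb, ()):
                truth.add(edge_key(a, b))
    return truth


# ---------------------------------------------------------------------------
# domain data


@dataclass
class DomainScenario:
    target_assignments: list[DomainAssignment]
    corpus_net: InteractionNetwork
    corpus_assignments: list[DomainAssignment]
    structural_ddis: list[DDI]


def make_domain_data(
    cfg: SimConfig, target_ids: list[str], n_domains: int = 40,
    n_corpus_proteins: int = 80, stream: int = 5,
) -> DomainScenario:
    """Domain assignments for target and corpus proteomes, an experimental
    corpus network correlated with shared domains, and a structural DDI
    table. Hit scores straddle the filter boundaries (20 / 1e-5 / 0.9) so
    threshold strictness is exercised."""
    rng = cfg.rng(stream)
    domains = [f"PF{i:05d}" for i in range(n_domains)]

    def assignments_for(pids: list[str]) -> list[DomainAssignment]:
        out = []
        for pid in pids:
            for _ in range(int(rng.integers(1, 4))):
                d = domains[int(rng.integers(n_domains))]
                # most hits pass the strict filter; a tail deliberately fails
                if rng.random() < 0.8:
                    score = float(rng.uniform(20.5, 300))
                    evalue = float(10 ** rng.uniform(-30, -5.5))
                    coverage = float(rng.uniform(0.905, 1.0))
                else:
                    score = float(rng.uniform(5, 20))
                    evalue = float(10 ** rng.uniform(-4.9, -1))
                    coverage = float(rng.uniform(0.3, 0.9))
                out.append(DomainAssignment(pid, d, score, evalue, coverage))
        return out

    corpus_ids = [f"cp{i:04d}" for i in range(n_corpus_proteins)]
    corpus_assignments = assignments_for(corpus_ids)
    target_assignments = assignments_for(list(target_ids))

    # interacting domain pairs drive the corpus edges
    true_pairs = set()
    while len(true_pairs) < max(4, n_domains // 5):
        x, y = rng.choice(n_domains, size=2, replace=False)
        true_pairs.add(edge_key(domains[int(x)], domains[int(y)]))
    strong: dict[str, set[str]] = {}
    for a in corpus_assignments:
        if a.score > 20 and a.evalue < 1e-5 and a.coverage > 0.9:
            strong.setdefault(a.protein, set()).add(a.domain)
    corpus_net = InteractionNetwork()
    ev = Evidence(kind="experimental", origin="corpus", score=1.0)
    for pid in corpus_ids:
        corpus_net.ensure_protein(pid)
    for p, q in combinations(corpus_ids, 2):
        dp, dq = strong.get(p, set()), strong.get(q, set())
        hit = any(
            edge_key(x, y) in true_pairs for x in dp for y in dq
        )
        if hit and rng.random() < 0.95:
            corpus_net.add_edge(p, q, ev)
        elif not hit and rng.random() < 0.01:
            corpus_net.add_edge(p, q, ev)

    structural = [
        DDI(domains=pair, source="structural", score=float(round(rng.uniform(0.1, 4.0), 2)))
        for pair in sorted(true_pairs)
    ]
    return DomainScenario(
        target_assignments=target_assignments,
        corpus_net=corpus_net,
        corpus_assignments=corpus_assignments,
        structural_ddis=structural,
    )


# ---------------------------------------------------------------------------
# expression


def make_expression(
    cfg: SimConfig,
    net: InteractionNetwork,
    groups: dict[str, int] | None = None,
    state: str = "FL",
    stream: int = 6,
) -> "ExpressionMatrix":
    """Gene x replicate signals with planted coexpression.

    Log-signals follow a shared-factor model: genes in the same group share
    a per-replicate latent factor with loading sqrt(rho), so any two genes
    of one group have log-signal correlation ``coexpression_rho``. Groups
    default to the network's connected components, so interacting pairs are
    correlated and pairs across components are not. Signals are strictly
    positive (exponentiated); detection p-values are Uniform(0, 0.06] for
    expressed genes and Uniform(0.06, 1] otherwise, with each gene expressed
    with probability ``detection_rate``.
    """
    from .states import ExpressionMatrix

    rng = cfg.rng((stream, sum(ord(c) for c in state)))
    genes = sorted(net.proteins)
    if groups is None:
        g = net.to_networkx(drop_self_loops=True)
        groups = {}
        for k, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                groups[node] = k
    rho = cfg.coexpression_rho
    t = cfg.n_replicates
    group_ids = sorted({groups.get(g_, -1) for g_ in genes})
    factors = {gid: rng.standard_normal(t) for gid in group_ids}
    # genes of one group share a baseline level (operon/regulon-like), so
    # interacting pairs also have similar expression LEVELS, not only
    # correlated profiles
    group_mu = {gid: rng.normal(np.log(500.0), 0.5) for gid in group_ids}
    sign = np.sign(rho) if rho != 0 else 1.0
    load = np.sqrt(abs(rho))
    resid = np.sqrt(1 - abs(rho))
    sig_rows, p_rows = [], []
    for gene in genes:
        gid = groups.get(gene, -1)
        if gid == -1:  # ungrouped genes are fully independent
            mu = rng.normal(np.log(500.0), 0.5)
            f = rng.standard_normal(t)
        else:
            mu = group_mu[gid] + rng.normal(0.0, 0.25)
            f = factors[gid]
        # alternate loading sign for negative rho so paired genes anti-correlate
        s = load if (sign > 0 or rng.random() < 0.5) else -load
        x = mu + s * f + resid * rng.standard_normal(t)
        sig_rows.append(np.exp(x))
        if rng.random() < cfg.detection_rate:
            p_rows.append(rng.uniform(np.nextafter(0, 1), 0.06, size=t))
        else:
            p_rows.append(rng.uniform(np.nextafter(0.06, 1), 1.0, size=t))
    cols = [f"rep{i+1}" for i in range(t)]
    signals = pd.DataFrame(np.vstack(sig_rows), index=genes, columns=cols)
    pvals = pd.DataFrame(np.vstack(p_rows), index=genes, columns=cols)
    return ExpressionMatrix(signals=signals, pvalues=pvals, state=state)


# ---------------------------------------------------------------------------
# SNF scenario: planted modules, seeds, TOMs


@dataclass
class SnfScenario:
    net: InteractionNetwork
    seeds: set[str]
    module_truth: dict[str, int]  # node -> planted module id (1-based)
    toms: list[str]
    background: set[str] = field(default_factory=set)


def make_snf_scenario(
    cfg: SimConfig,
    n_background: int = 20,
    seeds_per_module: int = 2,
    tom_modules: int = 2,
    tom_edges_per_module: int = 3,
    node_ids: list[str] | None = None,
    stream: int = 7,
) -> SnfScenario:
    """Network with dense planted modules around seed proteins plus planted
    Tie-of-Modules connectors wired into >= ``tom_modules`` modules, with
    sparse between-module and background edges. Ground truth (module
    assignment, seed list, TOM list) is emitted alongside. ``node_ids``
    draws node names from an existing proteome so annotations and
    expression attach to the same identifiers."""
    rng = cfg.rng(stream)
    lo, hi = cfg.module_size_range
    net = InteractionNetwork()
    ev = Evidence(kind="experimental", origin="snf-sim", score=1.0)
    module_truth: dict[str, int] = {}
    seeds: set[str] = set()
    counter = 0
    pool = list(node_ids) if node_ids is not None else None

    def new_node(prefix: str) -> str:
        nonlocal counter
        counter += 1
        if pool is not None:
            if not pool:
                raise ValueError("node_ids pool exhausted for the SNF scenario")
            return pool.pop(0)
        return f"{prefix}{counter:04d}"

    modules: list[list[str]] = []
    module_seeds: list[list[str]] = []
    for mid in range(1, cfg.n_planted_modules + 1):
        size = int(rng.integers(lo, hi + 1))
        members = [new_node("snf") for _ in range(size)]
        modules.append(members)
        for node in members:
            net.ensure_protein(node)
            module_truth[node] = mid
        for u, v in combinations(members, 2):
            if rng.random() < cfg.module_within_density:
                net.add_edge(u, v, ev)
        picked = [members[int(s)] for s in
                  rng.choice(size, size=min(seeds_per_module, size), replace=False)]
        module_seeds.append(picked)
        seeds.update(picked)
    # sparse between-module edges
    for a, b in combinations(range(len(modules)), 2):
        for u in modules[a]:
            for v in modules[b]:
                if rng.random() < cfg.module_between_density:
                    net.add_edge(u, v, ev)
    # planted TOMs: outside all modules, wired into several of them
    toms: list[str] = []
    for _ in range(cfg.n_toms):
        tom = new_node("tom")
        net.ensure_protein(tom)
        toms.append(tom)
        pick = rng.choice(len(modules), size=min(tom_modules, len(modules)), replace=False)
        for mi in np.atleast_1d(pick):
            members = modules[int(mi)]
            # wire through the module's seed hubs first (so the connector
            # survives seed-based core-subnetwork extraction), then fill with
            # other members
            order = module_seeds[int(mi)] + [
                m for m in members if m not in module_seeds[int(mi)]
            ]
            for target in order[: min(tom_edges_per_module, len(order))]:
                net.add_edge(tom, target, ev)
    # background nodes loosely attached to seeds (enter the SCSNW as neighbors)
    background: set[str] = set()
    seed_list = sorted(seeds)
    for _ in range(n_background):
        node = new_node("bg")
        net.ensure_protein(node)
        background.add(node)
        s = seed_list[int(rng.integers(len(seed_list)))]
        net.add_edge(node, s, ev)
    return SnfScenario(
        net=net, seeds=seeds, module_truth=module_truth, toms=toms, background=background
    )


# ---------------------------------------------------------------------------
# full fixture emission


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Write every pipeline input plus ground truth into ``outdir``;
    byte-identical across runs with the same config. Returns a manifest of
    file roles to paths."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    dag = make_go_dag(cfg)
    io.write_obo(dag, outdir / "go.obo")
    manifest["go_dag"] = "go.obo"

    proteins, ann = make_proteome(cfg, dag)
    io.write_annotations(ann, outdir / "annotations.tsv")
    manifest["annotations"] = "annotations.tsv"

    target_ids = sorted(proteins)
    truth: dict[str, object] = {}
    all_planted: set[tuple[str, str]] = set()
    for k in range(cfg.n_reference_species):
        sp = f"ref{k+1}"
        ref_net = make_reference_interactome(cfg, species=sp, stream=30 + k)
        io.write_network(ref_net, outdir / f"reference_{sp}.tsv", "tsv")
        groups = make_ortholog_map(
            cfg, target_ids, sorted(ref_net.proteins), species=sp, stream=40 + k
        )
        io.write_ortholog_groups(groups, outdir / f"orthologs_{sp}.tsv")
        planted = planted_interolog_edges(groups, ref_net)
        all_planted |= planted
        manifest[f"reference_{sp}"] = f"reference_{sp}.tsv"
        manifest[f"orthologs_{sp}"] = f"orthologs_{sp}.tsv"
    truth["planted_interolog_edges"] = sorted(map(list, all_planted))

    dom = make_domain_data(cfg, target_ids)
    io.write_domain_table(dom.target_assignments, outdir / "domains_target.tsv")
    io.write_domain_table(dom.corpus_assignments, outdir / "domains_corpus.tsv")
    io.write_network(dom.corpus_net, outdir / "corpus_ppis.tsv", "tsv")
    io.write_ddi_table(dom.structural_ddis, outdir / "ddi_structural.tsv")
    manifest.update(
        domains_target="domains_target.tsv",
        domains_corpus="domains_corpus.tsv",
        corpus_ppis="corpus_ppis.tsv",
        ddi_structural="ddi_structural.tsv",
    )

    # SNF scenario over proteome identifiers so annotations and expression
    # attach to the same proteins
    pool_rng = cfg.rng(70)
    pool = [target_ids[i] for i in pool_rng.permutation(len(target_ids))]
    snf = make_snf_scenario(cfg, node_ids=pool)
    io.write_network(snf.net, outdir / "snf_network.tsv", "tsv")
    io.write_seed_list(snf.seeds, outdir / "snf_seeds.txt")
    truth["snf_module_truth"] = {n: m for n, m in sorted(snf.module_truth.items())}
    truth["snf_toms"] = sorted(snf.toms)
    manifest.update(snf_network="snf_network.tsv", snf_seeds="snf_seeds.txt")

    for state, stream in (("FL", 60), ("SNF", 61)):
        expr = make_expression(cfg, snf.net, groups=snf.module_truth, state=state, stream=stream)
        io.write_expression(expr, outdir / f"expression_{state}.tsv")
        manifest[f"expression_{state}"] = f"expression_{state}.tsv"

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest["ground_truth"] = "ground_truth.json"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
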