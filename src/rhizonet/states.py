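"""Expression-defined state subnetworks and the transcription-difference statistic.

A gene counts as expressed in a physiological state (free-living cell or
symbiotic nitrogen-fixing bacteroid) only when strictly more than 80% of its
replicates have a detection p-value <= 0.06; its expression level is the mean
signal over those passing replicates. The state subnetwork keeps an
interaction only when both partners are expressed. The normalized
transcription-level difference of a pair,

    D_ij = |s_i - s_j| / (s_i + s_j),

lies in [0,1) and is compared between real interacting pairs and the control
group of all n^2 ordered protein pairs by a one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnnotationSet, InteractionNetwork, edge_key


@dataclass
class ExpressionMatrix:
    """Gene x replicate signals with paired detection p-values for one state."""

    signals: pd.DataFrame  # positive reals
    pvalues: pd.DataFrame  # in [0,1], same shape/index/columns
    state: str = ""

    def __post_init__(self) -> None:
        if self.signals.shape != self.pvalues.shape:
            raise ValueError("signal and p-value matrices must have the same shape")
        if not self.signals.index.equals(self.pvalues.index):
            raise ValueError("signal and p-value matrices must share a gene index")

    @property
    def genes(self) -> list[str]:
        return list(self.signals.index)

    @property
    def n_replicates(self) -> int:
        return self.signals.shape[1]

    def log_profiles(self) -> pd.DataFrame:
        """Log signals; the scale on which coexpression is measured."""
        return np.log(self.signals)


def expressed_genes(
    expr: ExpressionMatrix, p_max: float = 0.06, frac_min: float = 0.8
) -> tuple[set[str], dict[str, float]]:
    """Apply the detection filter and compute expression levels.

    A gene passes iff the fraction of replicates with p <= p_max is strictly
    greater than frac_min; its level is the mean signal over exactly those
    passing ("selected") replicates. Genes with zero replicates are excluded.
    """
    passing = expr.pvalues.le(p_max)
    n_rep = passing.shape[1]
    expressed: set[str] = set()
    levels: dict[str, float] = {}
    if n_rep == 0:
        return expressed, levels
    frac = passing.sum(axis=1) / n_rep
    for gene in expr.signals.index:
        if frac[gene] > frac_min:
            sel = passing.loc[gene]
            expressed.add(gene)
            levels[gene] = float(expr.signals.loc[gene, sel].mean())
    return expressed, levels


def induce_state_subnetwork(
    net: InteractionNetwork, present_set: set[str]
) -> InteractionNetwork:
    """Keep edges with BOTH endpoints present; nodes = endpoints of kept edges."""
    keep = [e for e in net.edges if e[0] in present_set and e[1] in present_set]
    return net.subnetwork_from_edges(keep)


def transcription_difference(level_i: float, level_j: float) -> float:
    """D = |s_i - s_j| / (s_i + s_j) for positive expression levels."""
    if level_i <= 0 or level_j <= 0:
        raise ValueError("expression levels must be positive")
    return abs(level_i - level_j) / (level_i + level_j)


def control_pair_count(n_proteins: int) -> int:
    """Size of the control group: all n^2 ordered pairs including self-pairs."""
    return n_proteins * n_proteins


def control_distribution(levels: dict[str, float]) -> np.ndarray:
    """D over all ordered pairs (i,j) including i=j (whose D is 0); n^2 values."""
    s = np.asarray(list(levels.values()), dtype=float)
    if np.any(s <= 0):
        raise ValueError("expression levels must be positive")
    d = np.abs(s[:, None] - s[None, :]) / (s[:, None] + s[None, :])
    return d.ravel()


def edge_differences(
    net: InteractionNetwork, levels: dict[str, float]
) -> np.ndarray:
    """D over network edges whose endpoints both have an expression level."""
    out = []
    for (u, v) in net.edges:
        if u in levels and v in levels:
            out.append(transcription_difference(levels[u], levels[v]))
    return np.asarray(out, dtype=float)


@dataclass
class PairComparison:
    median_ppi: float
    median_control: float
    n_ppi: int
    n_control: int
    pvalue: float


def compare_ppi_vs_control(
    net: InteractionNetwork, levels: dict[str, float]
) -> PairComparison:
    """One-sided rank-sum test: are interacting pairs' D values smaller than
    the D values of all pairwise combinations of the network's proteins?"""
    in_net = {g: s for g, s in levels.items() if g in net.proteins}
    ppi = edge_differences(net, in_net)
    ctrl = control_distribution(in_net)
    if ppi.size == 0 or ctrl.size == 0:
        raise ValueError("both the PPI and control groups must be nonempty")
    stat = stats.mannwhitneyu(ppi, ctrl, alternative="less")
    return PairComparison(
        median_ppi=float(np.median(ppi)),
        median_control=float(np.median(ctrl)),
        n_ppi=int(ppi.size),
        n_control=int(ctrl.size),
        pvalue=float(stat.pvalue),
    )


def per_cog_state_comparison(
    net_fl: InteractionNetwork,
    net_snf: InteractionNetwork,
    levels_fl: dict[str, float],
    levels_snf: dict[str, float],
    annotations: AnnotationSet,
    both_endpoints: bool = True,
) -> pd.DataFrame:
    """Per-COG-category FL-vs-SNF comparison of transcription differences.

    An edge belongs to category c iff both endpoints carry c (default), or at
    least one does with ``both_endpoints=False``. Categories with fewer than
    two qualifying edges in either state are skipped.
    """

    def cat_edges(net: InteractionNetwork, levels: dict[str, float], cat: str):
        vals = []
        for (u, v) in net.edges:
            if u not in levels or v not in levels:
                continue
            cu, cv = annotations.cog_of(u), annotations.cog_of(v)
            ok = (cat in cu and cat in cv) if both_endpoints else (cat in cu or cat in cv)
            if ok:
                vals.append(transcription_difference(levels[u], levels[v]))
        return np.asarray(vals)

    cats = sorted(
        {c for pid in list(net_fl.proteins) + list(net_snf.proteins) for c in annotations.cog_of(pid)}
    )
    rows = []
    for cat in cats:
        d_fl = cat_edges(net_fl, levels_fl, cat)
        d_snf = cat_edges(net_snf, levels_snf, cat)
        if d_fl.size < 2 or d_snf.size < 2:
            continue
        p = float(stats.ranksums(d_fl, d_snf).pvalue)
        rows.append(
            {
                "category": cat,
                "median_fl": float(np.median(d_fl)),
                "median_snf": float(np.median(d_snf)),
                "n_fl": int(d_fl.size),
                "n_snf": int(d_snf.size),
                "pvalue": p,
            }
        )
    return pd.DataFrame(rows, columns=["category", "median_fl", "median_snf", "n_fl", "n_snf", "pvalue"])
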