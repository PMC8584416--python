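"""Pairwise COG-category interaction enrichment as z-scores.

Edges whose endpoints are both COG-annotated are counted into a symmetric
category-pair matrix A (multi-COG proteins contribute to every category
combination of the pair). The same counting over an ensemble of
degree-preserving rewirings — node labels fixed, edges swapped — gives the
per-cell null mean and standard deviation, and

    Z_ij = (A_ij - <Rnd_ij>) / sigma(Rnd_ij).

Cells with sigma = 0 report Z = 0 when the real count equals the null mean
and a signed infinity sentinel otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AnnotationSet, InteractionNetwork
from .validation import rewire_degree_preserving


@dataclass
class ZScoreMatrix:
    z: pd.DataFrame
    null_mean: pd.DataFrame
    null_std: pd.DataFrame
    counts: pd.DataFrame
    n_nulls: int


def _categories(net: InteractionNetwork, annotations: AnnotationSet) -> list[str]:
    return sorted({c for pid in net.proteins for c in annotations.cog_of(pid)})


def pairwise_cog_counts(
    net: InteractionNetwork,
    annotations: AnnotationSet,
    categories: list[str] | None = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """Symmetric COG-pair interaction count matrix.

    Edges with any unannotated endpoint are dropped. Each remaining edge
    adds +1 (or 1/(|cats_u|*|cats_v|) with ``weighted=True``) to every
    unordered category combination {c_u, c_v}; within-category pairs land
    on the diagonal, counted once.
    """
    cats = categories if categories is not None else _categories(net, annotations)
    index = pd.Index(cats, name="category")
    mat = pd.DataFrame(0.0, index=index, columns=index)
    for (u, v) in net.edges:
        cu, cv = annotations.cog_of(u), annotations.cog_of(v)
        if not cu or not cv:
            continue
        w = 1.0 / (len(cu) * len(cv)) if weighted else 1.0
        seen: set[tuple[str, str]] = set()
        for a in cu:
            for b in cv:
                key = (a, b) if a <= b else (b, a)
                if key in seen:
                    continue
                seen.add(key)
                mat.loc[key[0], key[1]] += w
                if key[0] != key[1]:
                    mat.loc[key[1], key[0]] += w
    return mat


def cog_zscore_matrix(
    net: InteractionNetwork,
    annotations: AnnotationSet,
    n_nulls: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
    weighted: bool = False,
) -> ZScoreMatrix:
    """Z-score matrix of observed vs degree-preserving-null COG-pair counts."""
    if n_nulls < 2:
        raise ValueError("n_nulls must be >= 2")
    cats = _categories(net, annotations)
    observed = pairwise_cog_counts(net, annotations, cats, weighted)
    null_stack = np.empty((n_nulls, len(cats), len(cats)))
    for k in range(n_nulls):
        null_net = rewire_degree_preserving(net, swaps_per_edge, seed=seed * 100003 + k)
        null_stack[k] = pairwise_cog_counts(null_net, annotations, cats, weighted).to_numpy()
    mean = null_stack.mean(axis=0)
    std = null_stack.std(axis=0, ddof=0)
    obs = observed.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / std
    zero_sigma = std == 0
    z[zero_sigma & (obs == mean)] = 0.0
    z[zero_sigma & (obs > mean)] = np.inf
    z[zero_sigma & (obs < mean)] = -np.inf
    idx = observed.index
    return ZScoreMatrix(
        z=pd.DataFrame(z, index=idx, columns=idx),
        null_mean=pd.DataFrame(mean, index=idx, columns=idx),
        null_std=pd.DataFrame(std, index=idx, columns=idx),
        counts=observed,
        n_nulls=n_nulls,
    )


def heatmap_table(zmat: ZScoreMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write the category-labeled symmetric z-matrix as TSV; infinite
    sentinels serialize as 'inf' / '-inf'."""
    df = zmat.z if isinstance(zmat, ZScoreMatrix) else zmat
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_heatmap_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
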