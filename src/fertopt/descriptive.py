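"""Descriptive analyses: trait correlations and UPGMA treatment clustering.

Pearson correlations are computed among the three trait means across
treatments. For clustering, each trait column is z-scored (centered and
divided by its across-treatment standard deviation) and treatments are
agglomerated by average linkage (UPGMA) on Euclidean distances, yielding
an ultrametric tree that can be cut into a requested number of groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .dataset import TRAITS, TraitTable


def trait_correlations(table: TraitTable) -> pd.DataFrame:
    """3x3 Pearson correlation matrix of treatment means among traits."""
    if len(table.records) < 3:
        raise ValueError("correlations need at least 3 treatments")
    cols = {t: table.means(t) for t in TRAITS}
    mat = pd.DataFrame(index=TRAITS, columns=TRAITS, dtype=float)
    for a in TRAITS:
        for b in TRAITS:
            if np.std(cols[a]) == 0 or np.std(cols[b]) == 0:
                warnings.warn(f"zero-variance trait in pair ({a}, {b})")
                mat.loc[a, b] = np.nan
            else:
                mat.loc[a, b] = float(np.corrcoef(cols[a], cols[b])[0, 1])
    return mat


@dataclass
class ClusterTree:
    """UPGMA merge history over z-scored treatment profiles."""

    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: np.ndarray  # group label per treatment at the requested cut
    levels: np.ndarray  # (n, 3) dose triples, row-aligned with labels
    zscores: np.ndarray = field(repr=False)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def zscore_profiles(table: TraitTable) -> np.ndarray:
    """Per-trait z-scores of the treatment means (column SD, ddof=1)."""
    mat = np.column_stack([table.means(t) for t in TRAITS])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def upgma_cluster(table: TraitTable, groups: int) -> ClusterTree:
    """Average-linkage clustering of z-scored treatment profiles."""
    n = len(table.records)
    if not 1 <= groups <= n:
        raise ValueError(f"groups must be in [1, {n}]")
    z = zscore_profiles(table)
    link = hierarchy.linkage(z, method="average", metric="euclidean")
    labels = hierarchy.fcluster(link, t=groups, criterion="maxclust")
    return ClusterTree(linkage=link, labels=labels, levels=table.levels, zscores=z)
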