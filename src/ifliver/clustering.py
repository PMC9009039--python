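"""Two-way hierarchical clustering of the filtered gene set.

Genes (rows) and arrays (columns) are clustered agglomeratively on
row-standardized log2 expression.  Defaults are Euclidean distance with
complete linkage — the conventional defaults of R's ``hclust``, which this
stage mirrors; ``one_minus_pearson`` distance and ``average``/``ward``
linkage are available.  The gene dendrogram is cut at a fixed k (k = 4 in the
emulated design), with cluster ids 1..k assigned by dendrogram leaf order so
repeated runs label clusters identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError

log = logging.getLogger(__name__)

_METRICS = {"euclidean": "euclidean", "one_minus_pearson": "correlation"}
_LINKAGES = ("complete", "average", "ward")


@dataclass
class Dendrogram:
    """An agglomerative merge tree over labelled items."""

    labels: pd.Index
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, sd 1.

    Zero-variance rows become all-zero with a logged warning (they carry no
    profile information).
    """
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    zero = sd[:, 0] == 0
    if zero.any():
        log.warning("%d zero-variance row(s) standardized to all-zero", zero.sum())
    sd[zero] = 1.0
    out = pd.DataFrame((vals - mean) / sd, index=matrix.index, columns=matrix.columns)
    out.loc[zero] = 0.0
    return out


def _cluster(matrix: pd.DataFrame, distance: str, linkage: str) -> Dendrogram:
    if distance not in _METRICS:
        raise ValidationError(f"distance must be one of {sorted(_METRICS)}")
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValidationError("ward linkage requires euclidean distance")
    if len(matrix) < 2:
        raise ValidationError("clustering needs at least 2 items")
    d = pdist(matrix.to_numpy(dtype=float), metric=_METRICS[distance])
    z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(labels=matrix.index, linkage=z)


def cluster_genes(
    std_matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of gene rows."""
    return _cluster(std_matrix, distance, linkage)


def cluster_samples(
    std_matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of arrays (columns)."""
    return _cluster(std_matrix.T, distance, linkage)


def cut_k(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into k clusters; ids 1..k follow dendrogram leaf order."""
    if k < 1 or k > dendrogram.n_leaves:
        raise ValidationError(
            f"k must be in [1, {dendrogram.n_leaves}], got {k}"
        )
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    # relabel by order of first appearance along the dendrogram leaves
    leaves = hierarchy.leaves_list(dendrogram.linkage)
    relabel: dict[int, int] = {}
    for leaf in leaves:
        relabel.setdefault(int(raw[leaf]), len(relabel) + 1)
    assigned = np.array([relabel[int(c)] for c in raw])
    return pd.Series(assigned, index=dendrogram.labels, name="cluster")


def cluster_means(std_matrix: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Per-cluster, per-array mean of standardized expression.

    The result (clusters × arrays) is the "mean cluster expression" used for
    trait correlation.
    """
    missing = std_matrix.index.difference(assignment.index)
    if len(missing):
        raise ValidationError(
            f"assignment does not cover {len(missing)} gene(s): {list(missing[:10])}"
        )
    out = std_matrix.groupby(assignment.reindex(std_matrix.index).to_numpy()).mean()
    out.index = pd.Index(out.index, name="cluster")
    return out.sort_index()


def leaf_ordered_matrix(
    std_matrix: pd.DataFrame, gene_dend: Dendrogram, sample_dend: Dendrogram | None = None
) -> pd.DataFrame:
    """Heatmap-ready export: rows (and optionally columns) in leaf order."""
    rows = gene_dend.leaf_order()
    cols = sample_dend.leaf_order() if sample_dend is not None else list(std_matrix.columns)
    return std_matrix.loc[rows, cols]
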