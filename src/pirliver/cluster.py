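"""Sample clustering on signature expression and heatmap table export.

Samples are compared by Kendall rank correlation (tau-b, tie-corrected)
between their expression vectors over a chosen feature set; the
dissimilarity 1 - tau (range [0, 2]) feeds Ward agglomeration.  Ward on a
non-Euclidean dissimilarity is a standard approximation, used knowingly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau


def kendall_distance(matrix: pd.DataFrame, features=None) -> pd.DataFrame:
    """Pairwise 1 - Kendall tau-b between sample columns.

    Requires >= 2 features and >= 2 samples; a sample with constant
    expression has undefined tau and raises, naming the sample.
    """
    sub = matrix.loc[features] if features is not None else matrix
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 samples")
    cols = list(sub.columns)
    vals = sub.to_numpy(dtype=float)
    for j, c in enumerate(cols):
        if np.ptp(vals[:, j]) == 0:
            raise ValueError(f"sample {c!r} has constant expression; Kendall tau undefined")
    n = len(cols)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tau = kendalltau(vals[:, i], vals[:, j]).statistic
            D[i, j] = D[j, i] = 1.0 - tau
    return pd.DataFrame(D, index=cols, columns=cols)


@dataclass
class ClusterResult:
    """Ward tree over a sample dissimilarity matrix."""

    distance: pd.DataFrame
    linkage: np.ndarray
    sample_ids: list[str]

    def labels(self, k: int) -> pd.Series:
        lab = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.sample_ids, name="cluster")

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in leaves_list(self.linkage)]

    def to_newick(self) -> str:
        root = to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6f}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});"


def ward_cluster(distance: pd.DataFrame) -> ClusterResult:
    """Agglomerative Ward tree; merge heights are non-decreasing."""
    n = distance.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.allclose(distance.values, distance.values.T) or np.any(
        np.diag(distance.values) != 0
    ):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    condensed = squareform(distance.values, checks=False)
    Z = linkage(condensed, method="ward")
    return ClusterResult(distance=distance, linkage=Z, sample_ids=list(distance.columns))


def export_heatmap_table(
    matrix: pd.DataFrame,
    features=None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(RPM + pseudocount), median-centered per feature row."""
    sub = matrix.loc[features] if features is not None else matrix
    logged = np.log2(sub + pseudocount)
    return logged.sub(logged.median(axis=1), axis=0)
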