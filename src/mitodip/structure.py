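"""Tissue-level similarity: averaging, hierarchical clustering, correlation,
and corrgram-style PCA ordering.

Profiles are rows of (log2-)RPKM over the analyzed windows only.  Clustering
is agglomerative on Euclidean distances (complete linkage by default, the
default of the classic hclust implementation); the dendrogram can be exported
as Newick.  Sample ordering follows the corrgram convention: samples are
sorted by the angle of their loadings on the first two principal components
of the correlation matrix, with eigenvector signs fixed so the
largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ProfileSet",
    "average_profiles",
    "cluster_profiles",
    "ClusterResult",
    "correlation_matrix",
    "pca_order",
]


@dataclass
class ProfileSet:
    labels: list[str]
    matrix: np.ndarray  # labels x analyzed windows

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix must be 2-d with one row per label")
        if not np.isfinite(self.matrix).all():
            raise ValueError("profiles must be finite (drop ND windows first)")


def average_profiles(wm, grouping: dict[str, list[tuple[str, str]]], scale: str = "rpkm") -> ProfileSet:
    """Arithmetic mean profile per group over analyzed windows.

    `grouping` maps an output label (e.g. a tissue) to the member samples of a
    :class:`~mitodip.quantify.WindowMatrix`.
    """
    vals = wm.values(scale)[:, wm.analyzed_mask]
    labels, rows = [], []
    for label, members in grouping.items():
        if not members:
            raise ValueError(f"group {label!r} is empty")
        idx = [wm.sample_index(ind, tis) for ind, tis in members]
        labels.append(label)
        rows.append(vals[idx].mean(axis=0))
    return ProfileSet(labels=labels, matrix=np.vstack(rows))


def per_sample_profiles(wm, scale: str = "rpkm") -> ProfileSet:
    """One profile per sample, labelled "individual:tissue"."""
    vals = wm.values(scale)[:, wm.analyzed_mask]
    labels = [f"{ind}:{tis}" for ind, tis in wm.samples]
    return ProfileSet(labels=labels, matrix=vals.copy())


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    distances: np.ndarray  # condensed-form expanded to square

    def flat_clusters(self, k: int) -> dict[str, int]:
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def leaf_name(label: str) -> str:
            # quote labels carrying newick metacharacters
            if any(c in label for c in "(),:;' \t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{leaf_name(self.labels[node.id])}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"


def cluster_profiles(profiles: ProfileSet, metric: str = "euclidean", linkage: str = "complete") -> ClusterResult:
    """Agglomerative clustering of profiles; deterministic given input order."""
    if len(profiles.labels) < 2:
        raise ValueError("clustering requires at least two profiles")
    condensed = pdist(profiles.matrix, metric=metric)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterResult(
        labels=list(profiles.labels), linkage=Z, distances=squareform(condensed)
    )


def correlation_matrix(profiles: ProfileSet) -> np.ndarray:
    """Pearson correlation between profiles (rows); zero variance is an error."""
    if profiles.matrix.shape[1] < 2:
        raise ValueError("correlation requires at least two windows per profile")
    sd = profiles.matrix.std(axis=1)
    if (sd == 0).any():
        bad = [profiles.labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance profile(s): {bad}")
    r = np.corrcoef(profiles.matrix)
    return np.clip(r, -1.0, 1.0)


def pca_order(corr: np.ndarray) -> list[int]:
    """Corrgram-style ordering: angle of the first two principal axes.

    Eigenvectors of the correlation matrix are sign-fixed (largest-magnitude
    loading made positive); samples are ordered by ``atan2(PC2, PC1)``, ties
    broken by original index.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    pc1, pc2 = evecs[:, order[0]], evecs[:, order[1] if corr.shape[0] > 1 else order[0]]
    for pc in (pc1, pc2):
        i = int(np.argmax(np.abs(pc)))
        if pc[i] < 0:
            pc *= -1
    angles = np.arctan2(pc2, pc1)
    return sorted(range(corr.shape[0]), key=lambda i: (angles[i], i))
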