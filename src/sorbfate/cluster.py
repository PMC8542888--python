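"""Hierarchical clustering of sorption profiles.

Groups sorbents (or compounds) by the similarity of their mean K_bc
profiles.  Because K_bc spans more than an order of magnitude across
compounds and sorbents, profiles are log10-transformed and z-scored per
feature before average-linkage clustering on Euclidean distances; both
choices are switchable and recorded in the dendrogram's preprocessing
descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .batch import KbcMatrix
from .exceptions import ValidationError

__all__ = ["Dendrogram", "cluster_profiles", "cut_tree"]


@dataclass
class Dendrogram:
    """A hierarchical merge tree over labelled leaves.

    ``linkage_matrix`` is the scipy (n-1) x 4 merge table: each row holds
    (node a, node b, merge height, merged size).
    """

    linkage_matrix: np.ndarray
    labels: tuple
    method: str
    metric: str
    preprocessing: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> dict:
        """Flat labels for k clusters; see :func:`cut_tree`."""
        return cut_tree(self, k)

    def cophenetic_matrix(self) -> np.ndarray:
        """Square cophenetic distance matrix (an ultrametric for monotone linkages)."""
        return squareform(hierarchy.cophenet(self.linkage_matrix))

    def to_newick(self) -> str:
        """Newick serialisation; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return render(tree, tree.dist) + ";"

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(self.linkage_matrix, labels=list(self.labels), ax=ax, **kwargs)
        return ax


def _profile_matrix(matrix: KbcMatrix, axis: str, censored: str, standardize: bool):
    """Observations x features array after censoring policy and preprocessing."""
    steps = []
    if matrix.censored.to_numpy().any():
        if censored == "drop":
            drop_axis = "sorbents" if axis == "sorbents" else "compounds"
            matrix = matrix.drop_censored(axis=drop_axis)
            steps.append("censored cells: dropped affected " + drop_axis)
        elif censored == "impute":
            steps.append("censored cells: imputed at censoring bound")
        else:
            raise ValidationError("censored policy must be 'drop' or 'impute'")
    values = matrix.values.to_numpy(dtype=float)
    if axis == "sorbents":
        data = values.T
        labels = tuple(matrix.sorbents)
    elif axis == "compounds":
        data = values
        labels = tuple(matrix.compounds)
    else:
        raise ValidationError("axis must be 'sorbents' or 'compounds'")
    if np.any(~np.isfinite(data)) or np.any(data <= 0):
        raise ValidationError("K_bc matrix must be strictly positive and complete")
    data = np.log10(data)
    steps.append("log10 transform")
    if standardize:
        std = data.std(axis=0, ddof=0)
        centred = data - data.mean(axis=0)
        data = np.where(std > 0, centred / np.where(std > 0, std, 1.0), 0.0)
        steps.append("z-score per feature")
    return data, labels, "; ".join(steps)


def cluster_profiles(
    matrix: KbcMatrix,
    axis: str = "sorbents",
    method: str = "average",
    metric: str = "euclidean",
    censored: str = "drop",
    standardize: bool = True,
) -> Dendrogram:
    """Cluster sorbents (matrix columns) or compounds (rows) hierarchically.

    Deterministic: permuting the input order changes neither topology nor
    merge heights.  A constant matrix yields all-zero distances and a
    single-height tree (with a warning).
    """
    data, labels, preprocessing = _profile_matrix(matrix, axis, censored, standardize)
    if len(labels) < 2:
        raise ValidationError(f"need at least 2 items on axis {axis!r} to cluster")
    distances = pdist(data, metric=metric)
    if np.allclose(distances, 0.0):
        warnings.warn("all pairwise distances are zero; dendrogram is degenerate", stacklevel=2)
    linkage_matrix = hierarchy.linkage(distances, method=method)
    return Dendrogram(
        linkage_matrix=linkage_matrix,
        labels=labels,
        method=method,
        metric=metric,
        preprocessing=preprocessing,
    )


def cut_tree(dendrogram: Dendrogram, k: int) -> dict:
    """Flat partition of the leaves into k clusters following merge order.

    Returns a dict mapping leaf label to a cluster id in 1..k.
    """
    if not 1 <= k <= dendrogram.n_leaves:
        raise ValidationError(f"k must lie in [1, {dendrogram.n_leaves}], got {k}")
    flat = hierarchy.fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    return dict(zip(dendrogram.labels, (int(c) for c in flat)))
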