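"""Adjacent-interval change sets and location of the maximal-change window.

Two complementary readings of "where the big change happens" are computed
over the time series:

* per adjacent interval (t_i, t_{i+1}), the sets of genes moving up or down
  by at least the fold threshold — applied to every gene passing the
  minimum-read filter, irrespective of the other time points;
* the distance between consecutive sample columns (restricted to a gene
  subset, typically the fold-variation survivors), whose maximum flags the
  window period, corroborated by the two-cluster cut of a hierarchical
  dendrogram over the samples.

Clustering defaults follow the usual heatmap conventions: euclidean
distance, complete linkage, gene-wise centering on (the H/L coding is
mean-relative, and heatmap tools row-scale by default).  Centering is
exposed as a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .normalize import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "WindowReport",
    "interval_changed_genes",
    "sample_distance_matrix",
    "hierarchical_cluster",
    "max_change_window",
]

_METRICS = ("euclidean", "correlation")
_LINKAGES = ("complete", "average", "single")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence over samples.

    ``merges`` is the scipy linkage encoding: row k merges clusters
    ``merges[k, 0]`` and ``merges[k, 1]`` (ids < n are leaves, id n + k is
    the cluster formed at row k) at height ``merges[k, 2]``.
    """

    labels: tuple
    merges: np.ndarray
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> list[frozenset]:
        """Partition of the labels into k clusters, as frozensets."""
        assignments = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        clusters: dict[int, set] = {}
        for label, c in zip(self.labels, assignments):
            clusters.setdefault(c, set()).add(label)
        return sorted((frozenset(c) for c in clusters.values()), key=sorted)

    def cophenetic(self) -> np.ndarray:
        """Square matrix of merge heights at which label pairs first join."""
        return squareform(hierarchy.cophenet(self.merges))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.merges)

        def render(node):
            if node.is_leaf():
                return str(self.labels[node.id])
            left, right = node.get_left(), node.get_right()
            ldist = node.dist - left.dist
            rdist = node.dist - right.dist
            return f"({render(left)}:{ldist:g},{render(right)}:{rdist:g})"

        return render(tree) + ";"


@dataclass(frozen=True)
class WindowReport:
    """Everything the window analysis produces for one expression matrix."""

    intervals: tuple  # ordered (t_i, t_{i+1}) label pairs
    up_sets: dict
    down_sets: dict
    consecutive_distances: dict  # interval -> distance over the gene subset
    sample_distance: np.ndarray
    dendrogram: Dendrogram
    two_cluster_cut: tuple
    max_window: tuple
    fold: float
    metric: str
    centered: bool

    def interval_counts(self) -> dict:
        return {
            iv: (len(self.up_sets[iv]), len(self.down_sets[iv]))
            for iv in self.intervals
        }


def interval_changed_genes(
    expr: ExpressionMatrix, t_from: str, t_to: str, fold: float = 2.0
) -> tuple[set, set]:
    """Genes moving up / down by >= log2(fold) between two samples.

    Boundary inclusive; the two sets are disjoint for any fold > 1.
    """
    if not fold > 1:
        raise ValidationError("fold must be > 1")
    for label in (t_from, t_to):
        if label not in expr.sample_labels:
            raise ValidationError(f"unknown sample label {label!r}")
    if t_from == t_to:
        raise ValidationError("t_from and t_to must differ")
    j_from = expr.sample_labels.index(t_from)
    j_to = expr.sample_labels.index(t_to)
    delta = expr.values[:, j_to] - expr.values[:, j_from]
    threshold = np.log2(fold)
    up = {g for g, d in zip(expr.gene_ids, delta) if d >= threshold}
    down = {g for g, d in zip(expr.gene_ids, delta) if -d >= threshold}
    return up, down


def _column_matrix(
    expr: ExpressionMatrix, gene_subset, center: bool
) -> np.ndarray:
    sub = expr if gene_subset is None else expr.subset(gene_subset)
    if sub.n_genes == 0:
        raise ValidationError("gene subset is empty")
    values = sub.values
    if center:
        values = values - values.mean(axis=1, keepdims=True)
    return values


def sample_distance_matrix(
    expr: ExpressionMatrix,
    gene_subset=None,
    metric: str = "euclidean",
    center: bool = True,
) -> np.ndarray:
    """Pairwise distances between sample columns over a gene subset."""
    if metric not in _METRICS:
        raise ValidationError(f"metric must be one of {_METRICS}")
    values = _column_matrix(expr, gene_subset, center)
    if values.shape[1] < 2:
        raise ValidationError("need at least two samples")
    # samples are columns; pdist works on rows
    condensed = pdist(values.T, metric=metric)
    return squareform(condensed)


def hierarchical_cluster(
    dist: np.ndarray, labels, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix."""
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    dist = np.asarray(dist, dtype=float)
    labels = tuple(labels)
    if dist.shape != (len(labels), len(labels)):
        raise ValidationError("distance matrix shape must match labels")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    if dist.size and dist.min() < 0:
        raise ValidationError("distances must be non-negative")
    merges = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return Dendrogram(labels, merges, linkage)


def max_change_window(
    expr: ExpressionMatrix,
    gene_subset=None,
    metric: str = "euclidean",
    center: bool = True,
    linkage: str = "complete",
    fold: float = 2.0,
) -> WindowReport:
    """Flag the adjacent time-point interval with the largest change.

    Primary criterion: the distance between consecutive sample columns
    (restricted to ``gene_subset``) is maximal on the flagged interval.
    The two-cluster dendrogram cut is reported as corroboration.  Ties are
    broken toward the earliest interval, with a warning.

    ``up_sets`` / ``down_sets`` use the full ``expr`` (all genes passing
    the upstream min-read filter), not the subset: a gene can change
    twofold in one window regardless of its overall variation.
    """
    labels = expr.sample_labels
    if len(labels) < 2:
        raise ValidationError("need at least two time points")
    dist = sample_distance_matrix(expr, gene_subset, metric=metric, center=center)
    intervals = tuple(zip(labels[:-1], labels[1:]))
    consecutive = {
        (a, b): float(dist[labels.index(a), labels.index(b)]) for a, b in intervals
    }
    distances = np.array([consecutive[iv] for iv in intervals])
    best = int(np.argmax(distances))
    ties = np.flatnonzero(np.isclose(distances, distances[best]))
    if len(ties) > 1:
        warnings.warn(
            "maximal consecutive distance is tied across intervals "
            f"{[intervals[i] for i in ties]}; flagging the earliest",
            stacklevel=2,
        )
        best = int(ties[0])
    dendro = hierarchical_cluster(dist, labels, linkage=linkage)
    cut = tuple(dendro.cut(2)) if len(labels) >= 2 else ()
    up_sets, down_sets = {}, {}
    for a, b in intervals:
        up, down = interval_changed_genes(expr, a, b, fold=fold)
        up_sets[(a, b)] = up
        down_sets[(a, b)] = down
    return WindowReport(
        intervals=intervals,
        up_sets=up_sets,
        down_sets=down_sets,
        consecutive_distances=consecutive,
        sample_distance=dist,
        dendrogram=dendro,
        two_cluster_cut=cut,
        max_window=intervals[best],
        fold=fold,
        metric=metric,
        centered=center,
    )
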