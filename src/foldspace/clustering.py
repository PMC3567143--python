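"""Average-linkage clustering of a structure set under a distance criterion.

The focus (e.g. capsid) set is reduced to representatives by UPGMA
average-linkage hierarchical clustering of the structural distance matrix,
cut into the minimal number of clusters such that every within-cluster
pairwise distance is strictly below a threshold (default 0.6), followed by
medoid extraction.  Cutting a dendrogram into k clusters means undoing its
last k-1 merges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import squareform

DEFAULT_CLUSTER_THRESHOLD = 0.6


@dataclass
class ClusterPartition:
    """A flat partition of a structure set.

    ``labels`` maps id -> cluster index in 1..N; ``medoid_ids`` holds one
    representative per cluster (index c-1 for cluster c); ``max_intra`` is
    the largest within-cluster pairwise distance, strictly below
    ``threshold``.
    """

    labels: dict[str, int]
    n_clusters: int
    medoid_ids: list[str]
    max_intra: float
    threshold: float


class SeparationStats(NamedTuple):
    """Count/fraction of inter-cluster pairs closer than a probe cutoff."""

    count: int
    fraction: float
    n_inter_pairs: int


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    return D


def average_linkage_tree(D: np.ndarray) -> np.ndarray:
    """Unweighted average-linkage (UPGMA) merge tree of a distance matrix.

    Returns the merge list in scipy linkage format: n-1 rows of
    (cluster_i, cluster_j, height, size) with non-decreasing heights.
    """
    D = _validate_distance_matrix(D)
    if D.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    return linkage(squareform(D, checks=False), method="average")


def _labels_for_k(tree: np.ndarray, k: int) -> np.ndarray:
    return cut_tree(tree, n_clusters=k).ravel()


def medoids(
    labels: dict[str, int], D: np.ndarray, ids: Sequence[str]
) -> list[str]:
    """Per-cluster member minimizing total distance to co-members.

    Ties resolve to the lexicographically smallest id; singletons are their
    own medoid.  Returned in cluster order 1..N.
    """
    D = np.asarray(D, dtype=float)
    index_of = {d: i for i, d in enumerate(ids)}
    out: list[str] = []
    for c in range(1, max(labels.values()) + 1):
        members = sorted(d for d, lab in labels.items() if lab == c)
        rows = np.array([index_of[m] for m in members])
        sums = D[np.ix_(rows, rows)].sum(axis=1)
        out.append(members[int(np.argmin(sums))])  # argmin keeps first == smallest id
    return out


def optimal_partition(
    tree: np.ndarray,
    D: np.ndarray,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    ids: Sequence[str] | None = None,
) -> ClusterPartition:
    """Minimal number of clusters with all intra-cluster distances < threshold.

    Scans k = 1, 2, ... cutting the tree into k clusters (undoing the last
    k-1 merges) and returns the first k whose every within-cluster pairwise
    distance in ``D`` is strictly below ``threshold``.  k = n always
    satisfies the criterion.
    """
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids must match distance matrix size")
    for k in range(1, n + 1):
        raw = _labels_for_k(tree, k)
        max_intra = 0.0
        ok = True
        for c in np.unique(raw):
            rows = np.flatnonzero(raw == c)
            if len(rows) > 1:
                sub = D[np.ix_(rows, rows)]
                m = float(sub.max())
                max_intra = max(max_intra, m)
                if m >= threshold:
                    ok = False
                    break
        if ok:
            labels = {ids[i]: int(raw[i]) + 1 for i in range(n)}
            return ClusterPartition(
                labels=labels,
                n_clusters=int(raw.max()) + 1,
                medoid_ids=medoids(labels, D, ids),
                max_intra=max_intra,
                threshold=threshold,
            )
    raise AssertionError("unreachable: k = n always satisfies the criterion")


def separation_stats(
    partition: ClusterPartition,
    D: np.ndarray,
    ids: Sequence[str],
    probe_cutoff: float = 0.4,
) -> SeparationStats:
    """How many inter-cluster pairs are closer than ``probe_cutoff``.

    With no inter-cluster pairs (single cluster) the fraction is reported
    as 0 with ``n_inter_pairs == 0`` flagging the empty denominator.
    """
    D = np.asarray(D, dtype=float)
    lab = np.array([partition.labels[d] for d in ids])
    iu = np.triu_indices(len(ids), k=1)
    inter = lab[iu[0]] != lab[iu[1]]
    n_inter = int(inter.sum())
    count = int(np.sum(D[iu][inter] < probe_cutoff))
    fraction = count / n_inter if n_inter else 0.0
    return SeparationStats(count=count, fraction=fraction, n_inter_pairs=n_inter)


def tree_to_newick(tree: np.ndarray, ids: Sequence[str]) -> str:
    """Newick string of the merge tree with branch lengths from merge heights."""
    root = to_tree(tree)

    def _fmt(node, parent_height: float) -> str:
        branch = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{branch:.6f}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{branch:.6f}"

    return _fmt(root, root.dist) + ";"
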