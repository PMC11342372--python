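"""Complete-linkage agglomerative clustering under a distance threshold.

Structures are partitioned by hierarchical agglomeration on a precomputed
dissimilarity matrix: the pair of clusters with the smallest complete-linkage
(maximum inter-point) distance is merged repeatedly until that distance
exceeds the threshold, so every resulting cluster has diameter at most the
threshold.  Clusters that come out smaller than a minimum size can then be
pooled into a single "misfit" cluster, which participates in downstream
selection like any other.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["ClusterAssignment", "cluster_complete_linkage", "merge_small_clusters"]


@dataclass
class ClusterAssignment:
    """A flat partition of structures into clusters.

    ``labels[i]`` is the cluster id of structure ``i``; ids are contiguous
    from 0.  ``misfit_id`` is the id of the pooled small-cluster group, if
    one was created.
    """

    labels: np.ndarray
    threshold: float
    misfit_id: int | None = None
    min_size: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def _validate_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return 0.5 * (d + d.T)


def _relabel_by_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Renumber arbitrary labels to contiguous ids ordered by first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_complete_linkage(d: np.ndarray, threshold: float) -> ClusterAssignment:
    """Agglomerate with complete linkage until the merge distance exceeds
    ``threshold``.

    Every returned cluster has diameter (maximum intra-cluster distance) at
    most ``threshold``.  Cluster ids are contiguous and ordered by first
    occurrence, which makes the labelling deterministic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    d = _validate_dissimilarity(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 structures to cluster")
    z = linkage(squareform(d, checks=False), method="complete")
    raw = fcluster(z, t=threshold, criterion="distance")
    return ClusterAssignment(_relabel_by_first_occurrence(raw), threshold=float(threshold))


def merge_small_clusters(a: ClusterAssignment, min_size: int = 20) -> ClusterAssignment:
    """Pool every cluster smaller than ``min_size`` into one misfit cluster.

    Remaining clusters are renumbered contiguously (order of first
    occurrence); the misfit cluster, if created, takes the last id.  With no
    undersized clusters the assignment is returned unchanged (``misfit_id``
    unset).  Idempotent and count-preserving.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sizes = a.sizes()
    small = np.flatnonzero(sizes < min_size)
    if small.size == 0:
        return replace(a, min_size=min_size)
    keep = [cid for cid in range(a.n_clusters) if sizes[cid] >= min_size]
    if not keep:
        # Everything is undersized: one cluster holding all structures.
        labels = np.zeros_like(a.labels)
        return ClusterAssignment(labels, a.threshold, misfit_id=0, min_size=min_size)
    mapping = {cid: new for new, cid in enumerate(keep)}
    misfit = len(keep)
    labels = np.array([mapping.get(int(lab), misfit) for lab in a.labels])
    return ClusterAssignment(labels, a.threshold, misfit_id=misfit, min_size=min_size)
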