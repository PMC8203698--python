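"""Density-based clustering of treatment sequences on a precomputed TPD matrix.

Patient groups are found with hierarchical DBSCAN, which extracts the
DBSCAN clusterings at every density threshold and keeps the stable ones,
so no global epsilon has to be chosen.  Because the downstream predictor
averages over *all* groups, noise points are re-assigned to the cluster of
their nearest clustered neighbour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import HDBSCAN

__all__ = ["ClusterAssignment", "cluster_sequences", "resolve_noise"]

DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels aligned with dataset order; -1 marks unresolved noise."""

    labels: np.ndarray
    min_cluster_size: int

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def has_noise(self) -> bool:
        return bool((self.labels < 0).any())


def _validate_matrix(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {mat.shape}")
    if (mat < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(mat, mat.T, rtol=1e-9, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix diagonal is not zero")
    return mat


def cluster_sequences(
    distance_matrix: np.ndarray,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> ClusterAssignment:
    """Flat cluster extraction of the density hierarchy on precomputed distances.

    Deterministic for a fixed matrix.  Points the hierarchy rejects keep
    label -1 until :func:`resolve_noise` is applied.
    """
    mat = _validate_matrix(distance_matrix)
    if len(mat) < 2 * min_cluster_size:
        raise ValueError(
            f"need at least {2 * min_cluster_size} sequences for "
            f"min_cluster_size={min_cluster_size}, got {len(mat)}"
        )
    # copy=True: the backend otherwise overwrites the input matrix in place
    model = HDBSCAN(min_cluster_size=min_cluster_size, metric="precomputed", copy=True)
    labels = model.fit_predict(mat).astype(int)
    return ClusterAssignment(labels=labels, min_cluster_size=min_cluster_size)


def resolve_noise(assignment: ClusterAssignment, distance_matrix: np.ndarray) -> ClusterAssignment:
    """Re-label every noise point with its nearest non-noise neighbour's cluster.

    Ties in distance go to the lower cluster index.  If everything is
    noise, all points are collapsed into a single fallback cluster and a
    warning is issued.
    """
    mat = _validate_matrix(distance_matrix)
    labels = assignment.labels.copy()
    noise = np.where(labels < 0)[0]
    if len(noise) == 0:
        return assignment
    clustered = np.where(labels >= 0)[0]
    if len(clustered) == 0:
        warnings.warn(
            "all sequences were classified as noise; falling back to a single cluster",
            UserWarning,
            stacklevel=2,
        )
        return replace(assignment, labels=np.zeros_like(labels))
    for i in noise:
        d = mat[i, clustered]
        # nearest clustered neighbour; among equally near ones pick the
        # lowest cluster label for determinism
        candidates = clustered[d == d.min()]
        labels[i] = int(labels[candidates].min())
    return replace(assignment, labels=labels)
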