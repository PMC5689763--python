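"""Spatial statistics of NSC point patterns within a section.

Clustering is defined purely geometrically: two cells belong to the
same cluster when they are joined by a chain of pairwise distances
each <= the clustering radius (single-linkage connected components;
default radius 50 um).  The clustering index

    CI = 1 - n_clusters / n_cells

is 0 for complete dispersion and approaches its maximum 1 - 1/N when
all N cells form a single cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree, distance_matrix

from .cells import CellDetection

__all__ = [
    "ClusterResult",
    "pairwise_distances",
    "cluster_points",
    "clustering_index",
    "box_summary",
    "DEFAULT_CLUSTERING_RADIUS_UM",
]

DEFAULT_CLUSTERING_RADIUS_UM = 50.0


def _as_points(centroids: Sequence[CellDetection] | np.ndarray) -> np.ndarray:
    if isinstance(centroids, np.ndarray):
        pts = np.atleast_2d(centroids.astype(float))
    else:
        pts = np.array([c.xy for c in centroids], dtype=float)
        pts = pts.reshape(-1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (N, 2) array of planar coordinates")
    return pts


@dataclass(frozen=True)
class ClusterResult:
    """Single-linkage clustering of one section's NSC centroids."""

    labels: np.ndarray
    n_clusters: int
    ci: float
    clustering_radius_um: float


def pairwise_distances(
    centroids: Sequence[CellDetection] | np.ndarray,
) -> np.ndarray:
    """Symmetric Euclidean distance matrix (um), zero diagonal."""
    pts = _as_points(centroids)
    if len(pts) < 1:
        raise ValueError("at least one point required")
    return distance_matrix(pts, pts)


def cluster_points(
    centroids: Sequence[CellDetection] | np.ndarray,
    clustering_radius_um: float = DEFAULT_CLUSTERING_RADIUS_UM,
) -> ClusterResult:
    """Group points into single-linkage clusters at the given radius.

    Pairs at exactly the radius count as connected.  Labels are
    invariant to input ordering up to relabeling.
    """
    if clustering_radius_um < 0:
        raise ValueError("clustering_radius_um must be non-negative")
    pts = _as_points(centroids)
    n = len(pts)
    if n == 0:
        raise ValueError("clustering undefined for an empty point set")
    pairs = cKDTree(pts).query_pairs(r=clustering_radius_um, output_type="ndarray")
    data = np.ones(len(pairs))
    graph = coo_matrix(
        (data, (pairs[:, 0], pairs[:, 1])) if len(pairs) else ((), ((), ())),
        shape=(n, n),
    )
    n_clusters, labels = connected_components(graph, directed=False)
    return ClusterResult(
        labels=labels,
        n_clusters=int(n_clusters),
        ci=1.0 - n_clusters / n,
        clustering_radius_um=float(clustering_radius_um),
    )


def clustering_index(result: ClusterResult, n_cells: int) -> float:
    """CI = 1 - n_clusters / n_cells for the given cell count."""
    if n_cells < 1:
        raise ValueError("clustering index undefined for zero cells")
    return 1.0 - result.n_clusters / n_cells


def box_summary(values: Sequence[float]) -> dict[str, float]:
    """Median, quartiles, and 10th/90th percentiles of per-section values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    p10, q25, med, q75, p90 = np.percentile(arr, [10, 25, 50, 75, 90])
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "p10": float(p10),
        "p90": float(p90),
        "n": int(arr.size),
    }
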