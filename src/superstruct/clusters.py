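"""Fixed-ε cluster analysis: size filtering, densities, and shape descriptors.

Once a working ε has been chosen from the curve (typically the start of a
super-cluster regime), clusters are the Nmin=0 connected components at that
ε. Components below a minimum size are dissolved into "free" localizations —
a post-hoc filter on component size, not DBSCAN's core-point threshold.
Cluster density (retained clusters per area) and free-localization density
are measured inside circular or polygonal ROIs; per-cluster shape comes from
the 2D gyration tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import cluster_components
from .locio import CircleROI, LocalizationTable, PolygonROI

__all__ = [
    "ClusterSet",
    "DensityEstimate",
    "clusters_at_scale",
    "cluster_density",
    "free_density",
    "shape_descriptors",
]

FREE = -1  # label marking localizations not assigned to a retained cluster


@dataclass(frozen=True)
class DensityEstimate:
    count: int
    area_um2: float
    density_um2: float


@dataclass(frozen=True)
class ClusterSet:
    """Clusters at one ε after min-size filtering.

    ``labels`` holds a cluster id per localization, or ``FREE`` (−1) for
    points in dissolved components. ``clusters`` has one row per retained
    cluster: id, size, centroid_x/y (nm), gamma1/gamma2 (nm²), rg (nm),
    circularity.
    """

    epsilon: float
    min_size: int
    labels: np.ndarray
    clusters: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_free(self) -> int:
        return int(np.sum(self.labels == FREE))


def shape_descriptors(points: np.ndarray) -> dict[str, float]:
    """Gyration-tensor shape descriptors of a 2D point set.

    The tensor component for axes a, b is (1/2N²)·Σᵢ Σⱼ (aᵢ−aⱼ)(bᵢ−bⱼ),
    which equals the mean-centered second moment (biased covariance). Its
    eigenvalues γ1 ≥ γ2 give the squared major/minor semi-axes; the radius
    of gyration is Rg = √(γ1+γ2) and the circularity c = |γ1−γ2|/(γ1+γ2)
    (0 for an isotropic set, 1 for collinear points; defined as 0 when all
    points coincide). Both are rotation-invariant.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (N, 2) point array")
    if len(pts) < 2:
        raise ValueError("shape descriptors need at least 2 points")
    centered = pts - pts.mean(axis=0)
    tensor = centered.T @ centered / len(pts)
    g2, g1 = np.linalg.eigvalsh(tensor)  # ascending
    g1, g2 = float(max(g1, 0.0)), float(max(g2, 0.0))
    total = g1 + g2
    circ = abs(g1 - g2) / total if total > 0 else 0.0
    return {
        "gamma1": g1,
        "gamma2": g2,
        "rg": float(np.sqrt(total)),
        "circularity": circ,
    }


def clusters_at_scale(
    table: LocalizationTable, epsilon: float, min_size: int
) -> ClusterSet:
    """Detect clusters at one ε and dissolve components below ``min_size``.

    Components come from the Nmin=0 ε-neighborhood graph; those with fewer
    than ``min_size`` points are marked free. Per-cluster centroids and
    gyration shape descriptors are computed for every retained cluster.
    """
    if len(table) == 0:
        raise ValueError("cannot analyze an empty table")
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    raw = cluster_components(table, epsilon, nmin=0)
    xy = table.xy
    sizes = np.bincount(raw)
    keep_ids = np.flatnonzero(sizes >= min_size)
    labels = np.full(len(raw), FREE, dtype=np.int64)
    rows = []
    for new_id, old_id in enumerate(keep_ids):
        member = raw == old_id
        labels[member] = new_id
        pts = xy[member]
        centroid = pts.mean(axis=0)
        if len(pts) >= 2:
            shape = shape_descriptors(pts)
        else:
            shape = {"gamma1": 0.0, "gamma2": 0.0, "rg": 0.0, "circularity": 0.0}
        rows.append(
            {
                "id": new_id,
                "size": int(sizes[old_id]),
                "centroid_x": float(centroid[0]),
                "centroid_y": float(centroid[1]),
                **shape,
            }
        )
    columns = [
        "id", "size", "centroid_x", "centroid_y",
        "gamma1", "gamma2", "rg", "circularity",
    ]
    clusters = pd.DataFrame(rows, columns=columns)
    return ClusterSet(
        epsilon=float(epsilon), min_size=int(min_size),
        labels=labels, clusters=clusters,
    )


def cluster_density(
    cs: ClusterSet, roi: CircleROI | PolygonROI, table: LocalizationTable | None = None
) -> DensityEstimate:
    """Density of retained clusters whose centroid lies inside the ROI (μm⁻²)."""
    area = roi.area_um2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    if cs.n_clusters == 0:
        return DensityEstimate(count=0, area_um2=area, density_um2=0.0)
    centroids = cs.clusters[["centroid_x", "centroid_y"]].to_numpy()
    count = int(np.sum(roi.contains(centroids)))
    return DensityEstimate(count=count, area_um2=area, density_um2=count / area)


def free_density(
    cs: ClusterSet, roi: CircleROI | PolygonROI, table: LocalizationTable
) -> DensityEstimate:
    """Density of free (unclustered) localizations inside the ROI (μm⁻²)."""
    area = roi.area_um2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    free_xy = table.xy[cs.labels == FREE]
    count = int(np.sum(roi.contains(free_xy))) if len(free_xy) else 0
    return DensityEstimate(count=count, area_um2=area, density_um2=count / area)
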