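"""DBSCAN segmentation of localisation patterns and per-cluster morphology.

Cluster segmentation uses DBSCAN with a search radius of 20 nm and a
minimum of 3 neighbours — parameters suited to adhesion-protein clusters
imaged at ~20 nm localisation precision.  Neighbourhoods follow the
original DBSCAN convention and include the point itself: a core point
has at least ``min_neighbors`` points (itself included) within
``eps_nm``, so the smallest reportable cluster has ``min_neighbors``
members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN

from .geometry import NM2_PER_UM2, PointPattern

NOISE = -1


@dataclass(frozen=True)
class ClusterConfig:
    """DBSCAN parameters: search radius (nm) and minimum neighbour count."""

    eps_nm: float = 20.0
    min_neighbors: int = 3

    def __post_init__(self) -> None:
        if self.eps_nm <= 0:
            raise ValueError("search radius must be positive")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be at least 1")


def dbscan(pattern: PointPattern, cfg: ClusterConfig | None = None) -> np.ndarray:
    """Density-based cluster labels; noise points get label -1.

    Border points reachable from several clusters are assigned to the
    first-discovered cluster in input order (deterministic tie-break).
    """
    cfg = cfg or ClusterConfig()
    if pattern.n == 0:
        return np.zeros(0, dtype=int)
    # scikit-learn's min_samples also counts the point itself, matching
    # the neighbourhood convention documented above.
    model = DBSCAN(eps=cfg.eps_nm, min_samples=cfg.min_neighbors)
    return model.fit_predict(pattern.xy)


def cluster_stats(pattern: PointPattern, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster morphology: count, convex-hull area, density, centroid.

    Area is the convex hull of member coordinates in nm²; degenerate hulls
    (fewer than three points, or collinear members) have zero area and an
    undefined (NaN) density, flagged in ``degenerate_hull``.  Density is
    in molecules/µm².
    """
    labels = np.asarray(labels)
    if len(labels) != pattern.n:
        raise ValueError("labels and pattern have different lengths")
    rows = []
    for cid in np.unique(labels):
        if cid == NOISE:
            continue
        members = pattern.xy[labels == cid]
        area_nm2 = _hull_area(members)
        degenerate = area_nm2 == 0.0
        rows.append(
            {
                "cluster_id": int(cid),
                "n": int(len(members)),
                "area_nm2": area_nm2,
                "density_per_um2": np.nan if degenerate else len(members) / (area_nm2 / NM2_PER_UM2),
                "cx_nm": float(members[:, 0].mean()),
                "cy_nm": float(members[:, 1].mean()),
                "degenerate_hull": degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n", "area_nm2", "density_per_um2", "cx_nm", "cy_nm", "degenerate_hull"],
    )


def _hull_area(xy: np.ndarray) -> float:
    if len(xy) < 3:
        return 0.0
    try:
        hull = ConvexHull(xy)
    except QhullError:  # collinear or duplicate points
        return 0.0
    return float(hull.volume)  # in 2-D, "volume" is the area
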