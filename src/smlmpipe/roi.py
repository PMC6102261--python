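"""Region-of-interest analysis: densities inside and outside adhesive structures.

ROIs are labelled polygons in nm coordinates — typically a cell footprint
traced from a TIRF image plus the adhesive structures within it.  The
operations here answer the quantitative questions of the adhesion assay:
how dense are molecules inside vs outside adhesions, how does the ligand
density under the cell compare to the whole surface, and does a local
ligand density support tethering or spreading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import NM2_PER_UM2, PointPattern, Window

#: Empirical ligand-density thresholds (molecules/µm²) for cell behaviour,
#: exposed as constants: above TETHER_THRESHOLD_PER_UM2 cells tether to the
#: substratum; SPREAD_RANGE_PER_UM2 is the density range at which spreading
#: and adhesion formation begin.
TETHER_THRESHOLD_PER_UM2 = 0.8
SPREAD_RANGE_PER_UM2 = (4.0, 7.0)

VALID_ROI_LABELS = {"cell", "adhesion", "other"}


@dataclass
class Roi:
    """One labelled polygon, vertices in nm."""

    label: str
    vertices_nm: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_nm, dtype=float).reshape(-1, 2)
        self.vertices_nm = v
        if self.label not in VALID_ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}")
        if v.shape[0] < 3:
            raise ValueError(f"ROI {self.label!r} has fewer than 3 vertices")
        if not self.polygon.is_valid:
            raise ValueError(f"ROI {self.label!r} polygon is not simple/valid")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices_nm)


@dataclass
class RoiSet:
    """Collection of labelled ROIs for one field of view."""

    rois: list[Roi] = field(default_factory=list)

    def by_label(self, label: str) -> list[Roi]:
        return [r for r in self.rois if r.label == label]

    def union(self, label: str):
        """Shapely union of all polygons with the given label (overlaps merged)."""
        polys = [r.polygon for r in self.by_label(label)]
        return unary_union(polys) if polys else Polygon()

    # -- JSON schema: {"rois": [{"label": ..., "vertices_nm": [[x, y], ...]}]}
    def to_json(self, path) -> None:
        payload = {
            "rois": [
                {"label": r.label, "vertices_nm": r.vertices_nm.tolist()}
                for r in self.rois
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RoiSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [Roi(item["label"], np.asarray(item["vertices_nm"])) for item in payload["rois"]]
        )


@dataclass(frozen=True)
class DensityComparison:
    """Molecular densities inside vs outside a set of regions."""

    density_in_per_um2: float
    density_out_per_um2: float
    area_in_um2: float
    area_out_um2: float
    count_in: int
    count_out: int

    @property
    def ratio(self) -> float:
        """density_in / density_out (inf when nothing lies outside)."""
        if self.density_out_per_um2 == 0:
            return float("inf")
        return self.density_in_per_um2 / self.density_out_per_um2


def _covers_xy(geom, xy: np.ndarray) -> np.ndarray:
    """Closed point-in-polygon test (boundary counts as inside)."""
    if xy.size == 0:
        return np.zeros(0, dtype=bool)
    pts = shapely.points(xy[:, 0], xy[:, 1])
    return shapely.covers(geom, pts)


def assign_points_to_rois(pattern: PointPattern, rois: RoiSet) -> np.ndarray:
    """Label each point ``adhesion`` / ``cell`` / ``outside``.

    ``adhesion`` wins over ``cell`` where they overlap; points on a polygon
    boundary count as inside.  Returns an array of strings, one per point.
    """
    adhesion = rois.union("adhesion")
    cell = rois.union("cell")
    labels = np.full(pattern.n, "outside", dtype=object)
    if not cell.is_empty:
        labels[_covers_xy(cell, pattern.xy)] = "cell"
    if not adhesion.is_empty:
        labels[_covers_xy(adhesion, pattern.xy)] = "adhesion"
    return labels.astype(str)


def density_in_out(pattern: PointPattern, rois: RoiSet) -> DensityComparison:
    """Density inside adhesion ROIs vs inside the cell but outside adhesions.

    Mirrors the in/out-of-adhesive-structure bar comparisons of the adhesion
    assay: only points within the cell footprint participate.
    """
    adhesion = rois.union("adhesion")
    cell = rois.union("cell")
    if adhesion.is_empty or cell.is_empty:
        raise ValueError("need at least one cell and one adhesion ROI")
    outside_region = cell.difference(adhesion)
    area_in = adhesion.area / NM2_PER_UM2
    area_out = outside_region.area / NM2_PER_UM2
    if area_in == 0 or area_out == 0:
        raise ValueError("zero-area region in in/out density comparison")
    in_adhesion = _covers_xy(adhesion, pattern.xy)
    in_cell = _covers_xy(cell, pattern.xy)
    count_in = int(np.count_nonzero(in_adhesion & in_cell))
    count_out = int(np.count_nonzero(in_cell & ~in_adhesion))
    return DensityComparison(
        density_in_per_um2=count_in / area_in,
        density_out_per_um2=count_out / area_out,
        area_in_um2=area_in,
        area_out_um2=area_out,
        count_in=count_in,
        count_out=count_out,
    )


def surface_vs_undercell_density(
    pattern: PointPattern, cell_rois: RoiSet | Iterable[Roi], window: Window
) -> tuple[float, float]:
    """Average density over the full surface vs under the cell footprint(s).

    Overlapping cell polygons are unioned so no area is double counted.
    Returns ``(surface_per_um2, under_cell_per_um2)``.
    """
    if isinstance(cell_rois, RoiSet):
        cell = cell_rois.union("cell")
    else:
        cell = unary_union([r.polygon for r in cell_rois])
    surface = pattern.n / window.area_um2
    if cell.is_empty:
        raise ValueError("no cell polygons supplied")
    under_count = int(np.count_nonzero(_covers_xy(cell, pattern.xy)))
    under = under_count / (cell.area / NM2_PER_UM2)
    if pattern.n == 0:
        return 0.0, 0.0
    return surface, under


def classify_adhesion_support(
    local_density_per_um2: float,
    tether_threshold: float = TETHER_THRESHOLD_PER_UM2,
    spread_range: Sequence[float] = SPREAD_RANGE_PER_UM2,
) -> str:
    """Classify a local ligand density as ``none`` / ``tether`` / ``spread``.

    Cells tether only where the local density strictly exceeds the tether
    threshold, and spread once it reaches the lower end of the spreading
    range.  Thresholds are reported empirical constants, not fitted here.
    """
    if local_density_per_um2 < 0:
        raise ValueError("density must be non-negative")
    if local_density_per_um2 <= tether_threshold:
        return "none"
    if local_density_per_um2 < spread_range[0]:
        return "tether"
    return "spread"
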