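"""Second-order point-pattern statistics and density/spacing conversions.

Ripley's K counts, for each molecule, the neighbours within radius r,
normalised by the overall intensity; under complete spatial randomness
(CSR) its expectation is pi r^2, so the variance-stabilised L(r) - r is
zero for CSR and positive for clustered patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .geometry import NM2_PER_UM2, PointPattern, Window
from .roi import _covers_xy

EDGE_CORRECTIONS = ("none", "toroidal", "isotropic")


@dataclass
class RipleyCurve:
    """K, L and L - r over a radius grid (nm)."""

    radii_nm: np.ndarray
    k: np.ndarray
    edge_correction: str

    @property
    def l(self) -> np.ndarray:
        return np.sqrt(self.k / np.pi)

    @property
    def l_minus_r(self) -> np.ndarray:
        return self.l - self.radii_nm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_nm": self.radii_nm,
                "K": self.k,
                "L": self.l,
                "L_minus_r": self.l_minus_r,
            }
        )


def default_radii(start: float = 10.0, stop: float = 500.0, step: float = 10.0) -> np.ndarray:
    """Default radius grid, shared with the colocalisation analysis."""
    return np.arange(start, stop + step / 2, step)


def _isotropic_weights(xy: np.ndarray, d: np.ndarray, centre_idx: np.ndarray, window: Window) -> np.ndarray:
    """Ripley isotropic edge-correction weight per (centre, distance) pair.

    The weight is 2*pi over the angle of the circle of radius d centred on
    the point that lies inside the rectangular window (closed-form for a
    rectangle; valid for d below half the shorter side, which the radius
    guard enforces).
    """
    x = xy[centre_idx, 0]
    y = xy[centre_idx, 1]
    d1 = np.minimum(x - window.x_min, window.x_max - x)  # nearest vertical edge
    d2 = np.minimum(y - window.y_min, window.y_max - y)  # nearest horizontal edge
    with np.errstate(invalid="ignore"):
        a1 = np.where(d1 < d, 2 * np.arccos(np.clip(d1 / d, -1, 1)), 0.0)
        a2 = np.where(d2 < d, 2 * np.arccos(np.clip(d2 / d, -1, 1)), 0.0)
        corner = d1**2 + d2**2 < d**2
        alpha = np.where(
            corner,
            np.pi / 2
            + np.arccos(np.clip(d1 / d, -1, 1))
            + np.arccos(np.clip(d2 / d, -1, 1)),
            a1 + a2,
        )
    return 2 * np.pi / (2 * np.pi - alpha)


def ripley_k(
    pattern: PointPattern,
    radii_nm: np.ndarray | None = None,
    edge_correction: str = "toroidal",
) -> RipleyCurve:
    """Ripley K over a radius grid with the chosen edge correction.

    ``K(r) = area / (n (n-1)) * sum_i sum_{j != i} w_ij 1[d_ij <= r]``,
    the unbiased pairwise estimator.  ``toroidal`` wraps distances
    periodically (exact for synthetic periodic data); ``isotropic`` uses
    the circle-arc weight for rectangular windows; ``none`` applies no
    correction and is biased downward near edges.
    """
    if edge_correction not in EDGE_CORRECTIONS:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    if pattern.n < 2:
        raise ValueError("Ripley K needs at least two points")
    radii = np.asarray(radii_nm if radii_nm is not None else default_radii(), dtype=float)
    w = pattern.window
    short_side = min(w.width, w.height)
    if radii.max() > short_side / 4:
        warnings.warn(
            "max radius exceeds a quarter of the shorter window side; "
            "edge corrections degrade",
            stacklevel=2,
        )
    xy = pattern.xy - np.array([w.x_min, w.y_min])
    n = pattern.n
    norm = w.area_nm2 / (n * (n - 1))
    if edge_correction == "toroidal":
        tree = cKDTree(xy, boxsize=(w.width, w.height))
        counts = tree.count_neighbors(tree, radii) - n  # remove self pairs
        return RipleyCurve(radii, norm * counts, edge_correction)
    if edge_correction == "none":
        tree = cKDTree(xy)
        counts = tree.count_neighbors(tree, radii) - n
        return RipleyCurve(radii, norm * counts, edge_correction)
    # isotropic: per-pair weights
    tree = cKDTree(xy)
    pairs = tree.query_pairs(float(radii.max()), output_type="ndarray")
    if len(pairs) == 0:
        return RipleyCurve(radii, np.zeros_like(radii), edge_correction)
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
    win0 = Window(0.0, 0.0, w.width, w.height)
    wt = _isotropic_weights(xy, d, i, win0) + _isotropic_weights(xy, d, j, win0)
    order = np.argsort(d)
    d_sorted, wt_sorted = d[order], wt[order]
    cum = np.concatenate([[0.0], np.cumsum(wt_sorted)])
    counts = cum[np.searchsorted(d_sorted, radii, side="right")]
    return RipleyCurve(radii, norm * counts, edge_correction)


def point_density(pattern: PointPattern, region: Window | Polygon | np.ndarray | None = None) -> float:
    """Point count per µm² inside a window or polygon (boundary inclusive)."""
    if region is None:
        region = pattern.window
    if isinstance(region, Window):
        area_um2 = region.area_um2
        inside = region.contains(pattern.xy) if pattern.n else np.zeros(0, dtype=bool)
    else:
        poly = region if isinstance(region, Polygon) else Polygon(np.asarray(region, dtype=float))
        area_um2 = poly.area / NM2_PER_UM2
        inside = _covers_xy(poly, pattern.xy)
    if area_um2 <= 0:
        raise ValueError("region has zero area")
    return float(np.count_nonzero(inside)) / area_um2


def mean_nn_spacing_from_density(density_per_um2: float) -> float:
    """Mean nearest-neighbour spacing (nm) of a CSR pattern at the given density.

    For a homogeneous Poisson process of intensity lambda the mean
    nearest-neighbour distance is 1 / (2 sqrt(lambda)); e.g. 0.01
    molecules/µm² corresponds to 5 µm average spacing.  Exact inverse of
    ``density = 1 / (4 spacing^2)``.
    """
    if density_per_um2 <= 0:
        raise ValueError("density must be positive")
    spacing_um = 1.0 / (2.0 * np.sqrt(density_per_um2))
    return spacing_um * 1000.0


def nn_distances(pattern_a: PointPattern, pattern_b: PointPattern | None = None) -> np.ndarray:
    """Nearest-neighbour distance (nm) from each point of ``a`` to ``b``.

    With ``b`` omitted (or ``b is a``) the self nearest-neighbour
    distances are returned (the point itself excluded).
    """
    is_self = pattern_b is None or pattern_b is pattern_a
    target = pattern_a if is_self else pattern_b
    if target.n == 0:
        raise ValueError("target pattern is empty")
    tree = cKDTree(target.xy)
    if is_self:
        if pattern_a.n < 2:
            raise ValueError("self nearest-neighbour distances need at least two points")
        d, _ = tree.query(pattern_a.xy, k=2)
        return d[:, 1]
    d, _ = tree.query(pattern_a.xy, k=1)
    return np.atleast_1d(d)
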