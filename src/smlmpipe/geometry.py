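"""Core spatial containers: observation windows and planar point patterns.

All coordinates in this package are nanometres; intensities (densities) are
reported in molecules per square micrometre, the unit conventional for
surface ligand densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NM2_PER_UM2 = 1.0e6


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, in nm.

    Densities are defined relative to this region: a pattern of ``n`` points
    in a window of area ``A`` (µm²) has intensity ``n / A`` molecules/µm².
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Closed containment test for an (n, 2) coordinate array."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] <= self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] <= self.y_max)
        )

    def shrink(self, margin: float) -> "Window":
        """Window eroded by ``margin`` nm on every side."""
        return Window(
            self.x_min + margin,
            self.y_min + margin,
            self.x_max - margin,
            self.y_max - margin,
        )


@dataclass
class PointPattern:
    """A set of 2-D molecular coordinates observed in a rectangular window.

    Parameters
    ----------
    xy:
        ``(n, 2)`` array of coordinates in nm.
    window:
        Observation region; every point must lie inside it (boundary
        included).
    channel:
        Free-form channel label (e.g. ``"ligand"``, ``"paxillin"``).
    """

    xy: np.ndarray
    window: Window
    channel: str = ""

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "xy", xy)
        if xy.size and not self.window.contains(xy).all():
            raise ValueError("point pattern contains points outside its window")

    @property
    def n(self) -> int:
        return int(self.xy.shape[0])

    @property
    def intensity_per_um2(self) -> float:
        """Empirical intensity n / |window| in molecules/µm²."""
        return self.n / self.window.area_um2

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n
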