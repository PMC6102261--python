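"""Ground-truth scene generators for validating the SMLM analysis chain.

Every analysis stage in this package is exercised against data with known
structure: complete spatial randomness (CSR) for density calibration,
Thomas cluster processes for second-order statistics, paired two-colour
patterns for colocalisation scoring, adhesion scenes for ROI densitometry,
and rendered blinking movies for the localisation stage.

All generators take an integer seed (or a ``numpy.random.Generator``) and
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import NM2_PER_UM2, PointPattern, Window
from .roi import Roi, RoiSet, _covers_xy

__all__ = [
    "PhotophysicsParams",
    "DriftTrajectory",
    "FrameStack",
    "GroundTruthScene",
    "simulate_csr",
    "simulate_thomas",
    "simulate_two_color",
    "simulate_adhesion_scene",
    "render_blinking_stack",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PhotophysicsParams:
    """Blinking-fluorophore kinetics for the movie renderer.

    The on-time, off-gap and blink-count distributions are geometric
    (memoryless), the simplest kinetics compatible with threshold-based
    event grouping.  Defaults are a generic organic-dye regime:

    - ``mean_photons_per_frame``: 1000 photons detected per on-frame.
    - ``on_time_mean``: 2 frames per blink.
    - ``off_gap_mean``: 20 frames dark between blinks of one molecule.
    - ``n_blinks_mean``: 3 blinks per molecule before final bleaching.
    - ``background_rate``: 10 photons/pixel/frame of diffuse background.
    """

    mean_photons_per_frame: float = 1000.0
    on_time_mean: float = 2.0
    off_gap_mean: float = 20.0
    n_blinks_mean: float = 3.0
    background_rate: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "mean_photons_per_frame",
            "on_time_mean",
            "off_gap_mean",
            "n_blinks_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")


@dataclass
class DriftTrajectory:
    """Piecewise-linear lateral stage drift, anchored at zero displacement.

    ``knot_frames`` are strictly increasing frame indices; displacement
    between knots is linearly interpolated.  The displacement at frame 0
    is (0, 0) by construction.
    """

    knot_frames: np.ndarray
    knot_dx_nm: np.ndarray
    knot_dy_nm: np.ndarray

    def __post_init__(self) -> None:
        self.knot_frames = np.asarray(self.knot_frames, dtype=float)
        self.knot_dx_nm = np.asarray(self.knot_dx_nm, dtype=float)
        self.knot_dy_nm = np.asarray(self.knot_dy_nm, dtype=float)
        if np.any(np.diff(self.knot_frames) <= 0):
            raise ValueError("knot frames must be strictly increasing")
        if len({len(self.knot_frames), len(self.knot_dx_nm), len(self.knot_dy_nm)}) != 1:
            raise ValueError("knot arrays must have equal length")
        dx0, dy0 = self.displacement(np.array([0.0]))
        if abs(dx0[0]) > 1e-9 or abs(dy0[0]) > 1e-9:
            raise ValueError("drift displacement at frame 0 must be (0, 0)")

    @classmethod
    def zero(cls, n_frames: int) -> "DriftTrajectory":
        return cls(np.array([0, max(n_frames - 1, 1)]), np.zeros(2), np.zeros(2))

    @classmethod
    def linear(cls, n_frames: int, rate_x_nm: float, rate_y_nm: float) -> "DriftTrajectory":
        """Constant drift of (rate_x, rate_y) nm per frame."""
        last = max(n_frames - 1, 1)
        return cls(
            np.array([0, last]),
            np.array([0.0, rate_x_nm * last]),
            np.array([0.0, rate_y_nm * last]),
        )

    @property
    def frame_span(self) -> tuple[float, float]:
        return float(self.knot_frames[0]), float(self.knot_frames[-1])

    def displacement(self, frames) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (dx, dy) in nm at the given frame indices."""
        f = np.asarray(frames, dtype=float)
        dx = np.interp(f, self.knot_frames, self.knot_dx_nm)
        dy = np.interp(f, self.knot_frames, self.knot_dy_nm)
        return dx, dy


@dataclass
class FrameStack:
    """A camera movie: (n_frames, ny, nx) array of 16-bit counts."""

    frames: np.ndarray
    pixel_size_nm: float
    gain: float = 1.0

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class GroundTruthScene:
    """Two-channel adhesion scene with per-molecule ground-truth labels."""

    window: Window
    paxillin: PointPattern
    ligand: PointPattern
    roi_set: RoiSet
    paxillin_labels: pd.DataFrame  # columns: inside_adhesion (bool), roi_index (int)


# ---------------------------------------------------------------------------
# point-pattern generators
# ---------------------------------------------------------------------------

def simulate_csr(density_per_um2: float, window: Window, seed=None, channel: str = "") -> PointPattern:
    """Homogeneous Poisson (CSR) pattern at the requested intensity.

    The point count is Poisson(density x area) and positions are i.i.d.
    uniform over the window.
    """
    if density_per_um2 < 0:
        raise ValueError("density must be non-negative")
    rng = _rng(seed)
    n = rng.poisson(density_per_um2 * window.area_um2)
    xy = np.column_stack(
        [
            rng.uniform(window.x_min, window.x_max, n),
            rng.uniform(window.y_min, window.y_max, n),
        ]
    )
    return PointPattern(xy, window, channel)


def simulate_thomas(
    parent_density_per_um2: float,
    offspring_mean: float,
    cluster_sigma_nm: float,
    window: Window,
    seed=None,
    channel: str = "",
) -> PointPattern:
    """Thomas cluster process: Poisson parents with Gaussian offspring.

    Parents are drawn in a window buffered by 4 sigma so clusters whose
    centres fall just outside the observation region still contribute
    points, avoiding an edge deficit.  Offspring counts are
    Poisson(offspring_mean); offsets are isotropic Gaussian with standard
    deviation ``cluster_sigma_nm``.  Offspring falling outside the window
    are discarded (the pattern is the restriction of the stationary
    process to the window).
    """
    if parent_density_per_um2 <= 0 or cluster_sigma_nm <= 0:
        raise ValueError("parent density and cluster sigma must be positive")
    if offspring_mean < 0:
        raise ValueError("offspring mean must be non-negative")
    rng = _rng(seed)
    buffer = 4.0 * cluster_sigma_nm
    big = Window(
        window.x_min - buffer, window.y_min - buffer,
        window.x_max + buffer, window.y_max + buffer,
    )
    n_parents = rng.poisson(parent_density_per_um2 * big.area_um2)
    px = rng.uniform(big.x_min, big.x_max, n_parents)
    py = rng.uniform(big.y_min, big.y_max, n_parents)
    counts = rng.poisson(offspring_mean, n_parents)
    centres = np.repeat(np.column_stack([px, py]), counts, axis=0)
    xy = centres + rng.normal(0.0, cluster_sigma_nm, centres.shape)
    keep = window.contains(xy) if xy.size else np.zeros(0, dtype=bool)
    return PointPattern(xy[keep], window, channel)


def _reflect_into(window: Window, xy: np.ndarray) -> np.ndarray:
    """Reflect coordinates at the window boundary until inside."""
    out = xy.copy()
    for axis, (lo, hi) in enumerate(
        [(window.x_min, window.x_max), (window.y_min, window.y_max)]
    ):
        span = hi - lo
        v = np.mod(out[:, axis] - lo, 2 * span)
        out[:, axis] = lo + np.where(v > span, 2 * span - v, v)
    return out


TWO_COLOR_MODES = ("colocalized", "independent", "segregated")


def simulate_two_color(
    mode: str,
    density_per_um2: float,
    jitter_sigma_nm: float,
    window: Window,
    seed=None,
    base: str = "csr",
    cluster_sigma_nm: float = 50.0,
    offspring_mean: float = 30.0,
) -> tuple[PointPattern, PointPattern]:
    """Two-colour pattern pair with known cross-channel structure.

    - ``colocalized``: channel 2 is channel 1 displaced by isotropic
      Gaussian jitter (labelling/localisation error model), reflected at
      the window boundary.  The channel-1 base is CSR by default; with
      ``base="clustered"`` it is a Thomas field (cluster scale
      ``cluster_sigma_nm``, ``offspring_mean`` points per cluster, parent
      intensity chosen to reach the requested total density), emulating
      the locally clustered molecular maps on which colocalisation
      scoring is actually run.
    - ``independent``: two independent CSR draws at the same density.
    - ``segregated``: the channels confined to the left / right halves of
      the window (each at the requested density within its half).
    """
    if mode not in TWO_COLOR_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {TWO_COLOR_MODES}")
    if density_per_um2 <= 0:
        raise ValueError("density must be positive")
    if jitter_sigma_nm < 0:
        raise ValueError("jitter sigma must be non-negative")
    rng = _rng(seed)
    if mode == "colocalized":
        if base == "clustered":
            ch1 = simulate_thomas(
                density_per_um2 / offspring_mean,
                offspring_mean,
                cluster_sigma_nm,
                window,
                rng,
                channel="ch1",
            )
        elif base == "csr":
            ch1 = simulate_csr(density_per_um2, window, rng, channel="ch1")
        else:
            raise ValueError(f"unknown base {base!r}")
        xy2 = ch1.xy + rng.normal(0.0, jitter_sigma_nm, ch1.xy.shape)
        ch2 = PointPattern(_reflect_into(window, xy2), window, "ch2")
        return ch1, ch2
    if mode == "independent":
        return (
            simulate_csr(density_per_um2, window, rng, channel="ch1"),
            simulate_csr(density_per_um2, window, rng, channel="ch2"),
        )
    x_mid = 0.5 * (window.x_min + window.x_max)
    left = Window(window.x_min, window.y_min, x_mid, window.y_max)
    right = Window(x_mid, window.y_min, window.x_max, window.y_max)
    ch1 = simulate_csr(density_per_um2, left, rng, channel="ch1")
    ch2 = simulate_csr(density_per_um2, right, rng, channel="ch2")
    # re-house both patterns in the full window
    return (
        PointPattern(ch1.xy, window, "ch1"),
        PointPattern(ch2.xy, window, "ch2"),
    )


def _sample_in_polygon(polygon, density_per_um2: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson sample at the given intensity restricted to a shapely polygon."""
    if polygon.is_empty or density_per_um2 == 0:
        return np.zeros((0, 2))
    n = rng.poisson(density_per_um2 * polygon.area / NM2_PER_UM2)
    minx, miny, maxx, maxy = polygon.bounds
    frac = polygon.area / ((maxx - minx) * (maxy - miny))
    pts: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(int((n - got) / max(frac, 1e-6) * 1.2), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = _covers_xy(polygon, cand)
        hit = cand[inside]
        pts.append(hit[: n - got])
        got += min(len(hit), n - got)
    return np.vstack(pts) if pts else np.zeros((0, 2))


def simulate_adhesion_scene(
    window: Window,
    cell_polygon: np.ndarray,
    adhesion_polygons: list[np.ndarray],
    paxillin_density_in: float,
    paxillin_density_out: float,
    ligand_density: float,
    seed=None,
) -> GroundTruthScene:
    """Adhesion-protein channel concentrated in adhesion ROIs over a CSR ligand field.

    The paxillin channel is drawn at ``paxillin_density_in`` (µm⁻²) inside
    the union of adhesion polygons and at ``paxillin_density_out`` in the
    rest of the cell footprint; the ligand channel is CSR over the whole
    window, independent of the ROIs (the null in which adhesive structures
    do not sit on ligand hot-spots).
    """
    for d in (paxillin_density_in, paxillin_density_out, ligand_density):
        if d < 0:
            raise ValueError("densities must be non-negative")
    rng = _rng(seed)
    cell = Polygon(np.asarray(cell_polygon, dtype=float))
    adhesions = [Polygon(np.asarray(p, dtype=float)) for p in adhesion_polygons]
    for i, poly in enumerate(adhesions):
        if not cell.covers(poly):
            raise ValueError(f"adhesion polygon {i} is not contained in the cell polygon")
    adhesion_union = unary_union(adhesions)
    outside_region = cell.difference(adhesion_union)

    xy_in = _sample_in_polygon(adhesion_union, paxillin_density_in, rng)
    xy_out = _sample_in_polygon(outside_region, paxillin_density_out, rng)
    pax_xy = np.vstack([xy_in, xy_out])
    # ground-truth membership: which adhesion polygon each inside-point hit
    roi_index = np.full(len(pax_xy), -1, dtype=int)
    for i, poly in enumerate(adhesions):
        hit = _covers_xy(poly, xy_in)
        roi_index[: len(xy_in)][hit] = i
    labels = pd.DataFrame(
        {
            "inside_adhesion": np.r_[
                np.ones(len(xy_in), dtype=bool), np.zeros(len(xy_out), dtype=bool)
            ],
            "roi_index": roi_index,
        }
    )
    rois = RoiSet(
        [Roi("cell", np.asarray(cell_polygon, dtype=float))]
        + [Roi("adhesion", np.asarray(p, dtype=float)) for p in adhesion_polygons]
    )
    return GroundTruthScene(
        window=window,
        paxillin=PointPattern(pax_xy, window, "paxillin"),
        ligand=simulate_csr(ligand_density, window, rng, channel="ligand"),
        roi_set=rois,
        paxillin_labels=labels,
    )


# ---------------------------------------------------------------------------
# camera-frame renderer
# ---------------------------------------------------------------------------

def _integrated_gaussian_patch(
    u0: float, v0: float, sigma_px: float, cols: np.ndarray, rows: np.ndarray
) -> np.ndarray:
    """Fraction of a unit-flux Gaussian PSF falling in each listed pixel.

    ``u0, v0`` are continuous pixel coordinates (pixel (i, j) spans
    [i, i+1) x [j, j+1)); the PSF is integrated over each pixel with the
    error function.
    """
    s = sigma_px * np.sqrt(2.0)
    ex = 0.5 * (special.erf((cols + 1 - u0) / s) - special.erf((cols - u0) / s))
    ey = 0.5 * (special.erf((rows + 1 - v0) / s) - special.erf((rows - v0) / s))
    return ey[:, None] * ex[None, :]


def _blink_schedule(
    photophysics: PhotophysicsParams, n_frames: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """List of (first_frame, n_on_frames) blink intervals for one molecule."""
    n_blinks = rng.geometric(1.0 / photophysics.n_blinks_mean)
    start = int(rng.integers(0, n_frames))
    blinks = []
    frame = start
    for b in range(n_blinks):
        on = int(rng.geometric(1.0 / photophysics.on_time_mean))
        blinks.append((frame, on))
        frame += on + int(rng.geometric(1.0 / photophysics.off_gap_mean))
        if frame >= n_frames:
            break
    return [(f, on) for f, on in blinks if f < n_frames]


def render_blinking_stack(
    molecules: PointPattern,
    photophysics: PhotophysicsParams,
    psf_sigma_nm: float,
    pixel_size_nm: float,
    n_frames: int,
    drift: DriftTrajectory | None = None,
    fiducials: PointPattern | None = None,
    fiducial_photons_per_frame: float = 20000.0,
    shot_noise: bool = True,
    seed=None,
) -> tuple[FrameStack, pd.DataFrame]:
    """Render a blinking-emitter camera movie with per-event ground truth.

    Each molecule blinks according to ``photophysics``; on every on-frame
    it emits Poisson photons rendered as an error-function-integrated
    Gaussian PSF.  Fiducials emit a fixed flux on every frame.  Drift
    displaces all emitters.  Poisson background is added per pixel; with
    ``shot_noise`` the whole expected image is Poisson-resampled so pixel
    statistics match a photon-counting camera.

    Returns the stack plus a ground-truth table with one row per
    (molecule, frame) emission: ``molecule, frame, x_nm, y_nm, photons``
    where the position includes the drift applied at that frame.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if psf_sigma_nm < pixel_size_nm / 4:
        warnings.warn(
            "PSF sigma below pixel_size/4: the PSF is undersampled", stacklevel=2
        )
    rng = _rng(seed)
    window = molecules.window if molecules is not None else fiducials.window
    nx = int(np.ceil(window.width / pixel_size_nm))
    ny = int(np.ceil(window.height / pixel_size_nm))
    expected = np.zeros((n_frames, ny, nx))
    drift = drift or DriftTrajectory.zero(n_frames)
    sigma_px = psf_sigma_nm / pixel_size_nm
    halfw = max(int(np.ceil(4 * sigma_px)) + 1, 3)

    records: list[tuple[int, int, float, float, float]] = []

    def _paint(frame: int, x_nm: float, y_nm: float, photons: float) -> None:
        u0 = (x_nm - window.x_min) / pixel_size_nm
        v0 = (y_nm - window.y_min) / pixel_size_nm
        c0, c1 = int(np.floor(u0)) - halfw, int(np.floor(u0)) + halfw + 1
        r0, r1 = int(np.floor(v0)) - halfw, int(np.floor(v0)) + halfw + 1
        cols = np.arange(max(c0, 0), min(c1, nx))
        rows = np.arange(max(r0, 0), min(r1, ny))
        if len(cols) == 0 or len(rows) == 0:
            return
        patch = _integrated_gaussian_patch(u0, v0, sigma_px, cols, rows)
        expected[frame, rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1] += photons * patch

    for mol_id in range(molecules.n if molecules is not None else 0):
        x, y = molecules.xy[mol_id]
        for first, n_on in _blink_schedule(photophysics, n_frames, rng):
            for frame in range(first, min(first + n_on, n_frames)):
                photons = float(rng.poisson(photophysics.mean_photons_per_frame))
                dx, dy = drift.displacement([frame])
                xe, ye = x + dx[0], y + dy[0]
                _paint(frame, xe, ye, photons)
                records.append((mol_id, frame, xe, ye, photons))

    if fiducials is not None:
        for x, y in fiducials.xy:
            dx, dy = drift.displacement(np.arange(n_frames))
            for frame in range(n_frames):
                _paint(frame, x + dx[frame], y + dy[frame], fiducial_photons_per_frame)

    if shot_noise:
        counts = rng.poisson(expected + photophysics.background_rate)
    else:
        counts = expected + (
            rng.poisson(photophysics.background_rate, expected.shape)
            if photophysics.background_rate > 0
            else 0.0
        )
    stack = FrameStack(
        np.clip(np.round(counts), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        if shot_noise or photophysics.background_rate > 0
        else counts,  # keep float frames for exact noiseless rendering
        pixel_size_nm=pixel_size_nm,
    )
    truth = pd.DataFrame(
        records, columns=["molecule", "frame", "x_nm", "y_nm", "photons"]
    )
    return stack, truth
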