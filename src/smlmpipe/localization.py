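"""Camera stack -> drift-corrected, grouped localisation table.

The chain is the classical SMLM reconstruction pipeline:

1. per-frame event detection by thresholding the Gaussian-filtered image
   at ``I - M > k.S`` (I filtered intensity, M frame mean, S frame std);
2. least-squares fitting of an integrated 2-D Gaussian PSF to each
   candidate (joint fit when candidates overlap);
3. theoretical localisation precision from photon count, PSF width,
   pixel size and background (Mortensen MLE formula);
4. temporal grouping of repeated blinks of one molecule by a radius /
   on-time / off-gap rule;
5. fiducial-based drift estimation with a piecewise-linear model, and its
   application to the table.

Localisation tables are plain pandas DataFrames with nm coordinates; see
:mod:`smlmpipe.io` for the column contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from .synthetic import DriftTrajectory, FrameStack, _integrated_gaussian_patch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CameraModel:
    """Pixel geometry and photon conversion of the camera."""

    pixel_size_nm: float
    gain: float = 1.0  # counts per photon

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.gain <= 0:
            raise ValueError("pixel size and gain must be positive")


@dataclass(frozen=True)
class DetectionConfig:
    """Threshold detector settings.

    ``threshold_multiplier`` is the k in ``I - M > k.S``; the default k = 6
    keeps false detections negligible on typical backgrounds.  The fit
    window half-width is in pixels (window = (2h+1)^2 pixels); half-widths
    of 4 and 3 px suit bright organic dyes and photoactivatable proteins
    respectively.
    """

    gaussian_filter_sigma: float = 1.0
    threshold_multiplier: float = 6.0
    fit_window_halfwidth: int = 4

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold multiplier must be positive")
        if self.fit_window_halfwidth < 1:
            raise ValueError("fit window must be at least 3x3 pixels")


@dataclass(frozen=True)
class GroupingConfig:
    """Blink-grouping rule: spatial radius, max run length, max dark gap.

    Repeated events within ``radius_nm`` of each other are one molecule if
    each contiguous on-run lasts at most ``max_on`` frames and dark gaps
    between runs are at most ``max_gap`` frames.
    """

    radius_nm: float = 100.0
    max_on: int = 5
    max_gap: int = 50

    def __post_init__(self) -> None:
        if self.radius_nm <= 0 or self.max_on < 1 or self.max_gap < 0:
            raise ValueError("invalid grouping parameters")


@dataclass
class PsfFit:
    """Result of one 2-D Gaussian PSF fit (all lengths in nm, flux in photons)."""

    x_nm: float
    y_nm: float
    photons: float
    background_std: float  # sqrt(background photons / pixel)
    sigma_nm: float
    residual: float
    frame: int = -1


def detect_events(stack: FrameStack, cfg: DetectionConfig) -> pd.DataFrame:
    """Find candidate emitters: frame, pixel position and filtered peak intensity.

    Per frame the image is Gaussian filtered; local maxima whose filtered
    intensity exceeds the frame mean by ``k`` standard deviations are
    candidates.  Maxima closer than one fit window are merged into the
    brighter one, so each emitter yields a single candidate.
    """
    rows: list[tuple[int, int, int, float]] = []
    w = 2 * cfg.fit_window_halfwidth + 1
    for t in range(stack.n_frames):
        img = stack.frames[t].astype(float)
        filt = ndimage.gaussian_filter(img, cfg.gaussian_filter_sigma)
        m, s = filt.mean(), filt.std()
        if s == 0:
            continue  # constant frame: nothing can exceed the threshold
        is_max = filt == ndimage.maximum_filter(filt, size=3)
        hot = is_max & (filt - m > cfg.threshold_multiplier * s)
        rr, cc = np.nonzero(hot)
        if len(rr) == 0:
            continue
        order = np.argsort(filt[rr, cc])[::-1]
        kept: list[tuple[int, int]] = []
        for idx in order:
            r, c = int(rr[idx]), int(cc[idx])
            if all(max(abs(r - kr), abs(c - kc)) >= w for kr, kc in kept):
                kept.append((r, c))
                rows.append((t, r, c, float(filt[r, c])))
    return pd.DataFrame(rows, columns=["frame", "row", "col", "intensity"])


def _psf_model(params: np.ndarray, n_emitters: int, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Sum of integrated Gaussians plus constant background, in counts."""
    model = np.full((len(rows), len(cols)), params[-1])
    for k in range(n_emitters):
        amp, u0, v0, sigma = params[4 * k: 4 * k + 4]
        model += amp * _integrated_gaussian_patch(u0, v0, abs(sigma), cols, rows)
    return model


def fit_psf(
    frame: np.ndarray,
    candidates: pd.DataFrame | tuple[int, int] | list[tuple[int, int]],
    camera: CameraModel,
    cfg: DetectionConfig,
    max_joint: int = 3,
) -> list[PsfFit]:
    """Least-squares integrated-Gaussian fit of one fit window.

    ``candidates`` is one (row, col) pixel or several; candidates sharing
    a window are fitted jointly as a multi-emitter model.  More than
    ``max_joint`` overlapping candidates are discarded (logged).  Centres
    are returned in nm with the pixel (i, j) centre at ((i+.5)a, (j+.5)a).
    """
    if isinstance(candidates, tuple):
        cand = [candidates]
    elif isinstance(candidates, pd.DataFrame):
        cand = list(zip(candidates["row"].astype(int), candidates["col"].astype(int)))
    else:
        cand = list(candidates)
    if len(cand) > max_joint:
        logger.info("discarding %d-emitter window (joint-fit limit %d)", len(cand), max_joint)
        return []
    h = cfg.fit_window_halfwidth
    r_cent = int(round(np.mean([r for r, _ in cand])))
    c_cent = int(round(np.mean([c for _, c in cand])))
    rows = np.arange(max(r_cent - h, 0), min(r_cent + h + 1, frame.shape[0]))
    cols = np.arange(max(c_cent - h, 0), min(c_cent + h + 1, frame.shape[1]))
    if len(rows) < 3 or len(cols) < 3:
        return []
    data = frame[np.ix_(rows, cols)].astype(float)

    p0: list[float] = []
    for r, c in cand:
        amp0 = max(float(frame[r, c]) - float(np.median(data)), 1.0)
        p0 += [amp0 * 4.0, c + 0.5, r + 0.5, 1.3]
    p0.append(float(np.median(data)))

    # Poisson-weighted residuals (weights refreshed from the model inside
    # the solver) make the least-squares solution approximate the photon
    # maximum-likelihood estimate, whose precision the Mortensen formula
    # predicts; unweighted LS would be noticeably less efficient.
    def resid(p: np.ndarray) -> np.ndarray:
        model = _psf_model(p, len(cand), cols, rows)
        return ((model - data) / np.sqrt(np.maximum(model, 1.0))).ravel()

    try:
        sol = optimize.least_squares(resid, np.asarray(p0), method="lm", max_nfev=400)
    except Exception:  # pragma: no cover - pathological windows
        logger.info("PSF fit failed to start; window discarded")
        return []
    if not sol.success or not np.all(np.isfinite(sol.x)):
        logger.info("PSF fit did not converge; window discarded")
        return []
    fits: list[PsfFit] = []
    a = camera.pixel_size_nm
    bkg_counts = max(float(sol.x[-1]), 0.0)
    for k in range(len(cand)):
        amp, u0, v0, sigma = sol.x[4 * k: 4 * k + 4]
        sigma = abs(float(sigma))
        if amp <= 0 or sigma <= 0:
            continue
        if not (cols[0] <= u0 <= cols[-1] + 1 and rows[0] <= v0 <= rows[-1] + 1):
            continue  # centre escaped the window: unreliable
        fits.append(
            PsfFit(
                x_nm=float(u0) * a,
                y_nm=float(v0) * a,
                photons=float(amp) / camera.gain,
                background_std=float(np.sqrt(bkg_counts / camera.gain)),
                sigma_nm=sigma * a,
                residual=float(np.sqrt(np.mean(sol.fun**2))),
                frame=-1,
            )
        )
    return fits


def localization_precision(fit: PsfFit, camera: CameraModel) -> float:
    """Theoretical localisation precision (nm) for a fitted emitter.

    Maximum-likelihood precision for an integrated-Gaussian PSF on a
    pixelated detector with uniform background:

        sigma_loc^2 = (sigma_a^2 / N) * (16/9 + 8 pi sigma_a^2 b^2 / (N a^2))

    with sigma_a^2 = sigma^2 + a^2/12 (pixelation-corrected PSF width),
    N the photon count, a the pixel size and b^2 the background photons
    per pixel.
    """
    if fit.photons <= 0:
        raise ValueError("photon count must be positive")
    a = camera.pixel_size_nm
    sigma_a2 = fit.sigma_nm**2 + a**2 / 12.0
    n = fit.photons
    b2 = fit.background_std**2
    return float(np.sqrt(sigma_a2 / n * (16.0 / 9.0 + 8.0 * np.pi * sigma_a2 * b2 / (n * a**2))))


def localize_stack(
    stack: FrameStack,
    camera: CameraModel,
    cfg: DetectionConfig | None = None,
    channel: str = "",
) -> pd.DataFrame:
    """Detect and fit every frame; returns a localisation table.

    Candidates within one fit window of each other in the same frame are
    fitted jointly.  Columns: frame, x_nm, y_nm, photons, bkg, sigma_nm,
    precision_nm, channel, group_id (-1, ungrouped).
    """
    cfg = cfg or DetectionConfig()
    cand = detect_events(stack, cfg)
    w = 2 * cfg.fit_window_halfwidth + 1
    out: list[dict] = []
    for t, sub in cand.groupby("frame"):
        frame = stack.frames[int(t)].astype(float)
        pix = list(zip(sub["row"].astype(int), sub["col"].astype(int)))
        # union overlapping candidates into joint-fit groups
        groups: list[list[tuple[int, int]]] = []
        for p in pix:
            for g in groups:
                if any(max(abs(p[0] - q[0]), abs(p[1] - q[1])) < 2 * w for q in g):
                    g.append(p)
                    break
            else:
                groups.append([p])
        for g in groups:
            for fit in fit_psf(frame, g, camera, cfg):
                fit.frame = int(t)
                out.append(
                    {
                        "frame": int(t),
                        "x_nm": fit.x_nm,
                        "y_nm": fit.y_nm,
                        "photons": fit.photons,
                        "bkg": fit.background_std,
                        "sigma_nm": fit.sigma_nm,
                        "precision_nm": localization_precision(fit, camera),
                        "channel": channel,
                        "group_id": -1,
                    }
                )
    return pd.DataFrame(
        out,
        columns=[
            "frame", "x_nm", "y_nm", "photons", "bkg",
            "sigma_nm", "precision_nm", "channel", "group_id",
        ],
    )


# ---------------------------------------------------------------------------
# temporal grouping
# ---------------------------------------------------------------------------

class _Group:
    __slots__ = ("indices", "wx", "wy", "w", "last_frame", "run_len")

    def __init__(self, idx: int, x: float, y: float, photons: float, frame: int):
        self.indices = [idx]
        self.w = photons
        self.wx = photons * x
        self.wy = photons * y
        self.last_frame = frame
        self.run_len = 1

    @property
    def x(self) -> float:
        return self.wx / self.w

    @property
    def y(self) -> float:
        return self.wy / self.w

    def add(self, idx: int, x: float, y: float, photons: float, frame: int, same_run: bool):
        self.indices.append(idx)
        self.w += photons
        self.wx += photons * x
        self.wy += photons * y
        self.run_len = self.run_len + 1 if same_run else 1
        self.last_frame = frame


def group_localizations(
    table: pd.DataFrame, cfg: GroupingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge repeated blinks of one molecule into single records.

    Events chain into one group when they lie within ``radius_nm`` of the
    group's running photon-weighted centre and are temporally compatible:
    contiguous frame runs of at most ``max_on`` frames, separated by dark
    gaps of at most ``max_gap`` frames.  A run that would exceed
    ``max_on`` starts a new group (conservative split).  Two events in the
    same frame are always distinct molecules.

    Returns ``(labelled, merged)``: the input with a ``group_id`` column,
    and one merged record per group (photon-weighted mean position, summed
    photons, first frame, inverse-variance-combined precision).
    """
    cfg = cfg or GroupingConfig()
    if len(table) == 0:
        empty = table.copy()
        return empty, empty
    df = table.sort_values(["frame", "x_nm", "y_nm"], kind="mergesort").reset_index()
    open_groups: list[_Group] = []
    closed: list[_Group] = []
    for i in range(len(df)):
        frame = int(df.at[i, "frame"])
        x, y, ph = float(df.at[i, "x_nm"]), float(df.at[i, "y_nm"]), float(df.at[i, "photons"])
        # retire groups whose dark gap can no longer be bridged
        still_open = []
        for g in open_groups:
            if frame - g.last_frame - 1 > cfg.max_gap:
                closed.append(g)
            else:
                still_open.append(g)
        open_groups = still_open
        best: _Group | None = None
        best_d = cfg.radius_nm
        for g in open_groups:
            if g.last_frame == frame:
                continue  # one emission per molecule per frame
            consecutive = frame == g.last_frame + 1
            if consecutive and g.run_len + 1 > cfg.max_on:
                continue
            d = float(np.hypot(g.x - x, g.y - y))
            if d <= best_d:
                best, best_d = g, d
        if best is None:
            open_groups.append(_Group(i, x, y, ph, frame))
        else:
            best.add(i, x, y, ph, frame, same_run=(frame == best.last_frame + 1))
    closed.extend(open_groups)

    group_ids = np.empty(len(df), dtype=int)
    merged_rows = []
    has_prec = "precision_nm" in df.columns
    for gid, g in enumerate(closed):
        members = df.loc[g.indices]
        group_ids[g.indices] = gid
        row = {
            "frame": int(members["frame"].min()),
            "x_nm": g.x,
            "y_nm": g.y,
            "photons": float(members["photons"].sum()),
            "n_events": len(g.indices),
            "group_id": gid,
        }
        if "channel" in df.columns:
            row["channel"] = members["channel"].iloc[0]
        if has_prec:
            w = members["photons"].to_numpy()
            s = members["precision_nm"].to_numpy()
            row["precision_nm"] = float(np.sqrt(np.sum((w * s) ** 2)) / np.sum(w))
        merged_rows.append(row)
    labelled = df.copy()
    labelled["group_id"] = group_ids
    labelled = labelled.sort_values("index").set_index("index")
    labelled.index.name = table.index.name
    merged = pd.DataFrame(merged_rows).sort_values("group_id").reset_index(drop=True)
    return labelled, merged


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------

def estimate_drift(
    table: pd.DataFrame,
    fiducial_seeds: np.ndarray,
    knot_spacing: int = 100,
    search_radius_nm: float = 500.0,
) -> DriftTrajectory:
    """Fiducial-based piecewise-linear drift estimate.

    Each fiducial is tracked through the movie by nearest-neighbour
    linking from its seed position (the track position is updated every
    frame, so slow drifts far exceeding ``search_radius_nm`` in total are
    followed).  Displacements relative to each fiducial's first
    observation are averaged across fiducials, then averaged within knot
    spans of ``knot_spacing`` frames and anchored to zero at frame 0.
    """
    seeds = np.asarray(fiducial_seeds, dtype=float).reshape(-1, 2)
    if len(seeds) == 0:
        raise ValueError("at least one fiducial seed is required")
    frames = np.sort(table["frame"].unique())
    xy = table[["x_nm", "y_nm"]].to_numpy()
    by_frame = {int(f): np.nonzero(table["frame"].to_numpy() == f)[0] for f in frames}

    # per-fiducial displacement samples: frame -> (dx, dy)
    samples: list[tuple[int, float, float]] = []
    for s_i, seed in enumerate(seeds):
        pos = seed.copy()
        origin: np.ndarray | None = None
        found_any = False
        for f in frames:
            idx = by_frame[int(f)]
            d = np.hypot(xy[idx, 0] - pos[0], xy[idx, 1] - pos[1])
            j = int(np.argmin(d))
            if d[j] > search_radius_nm:
                continue
            pos = xy[idx[j]].copy()
            if origin is None:
                origin = pos.copy()
            found_any = True
            samples.append((int(f), pos[0] - origin[0], pos[1] - origin[1]))
        if not found_any:
            near = np.hypot(xy[:, 0] - seed[0], xy[:, 1] - seed[1])
            nearest = np.sort(near)[:5]
            raise ValueError(
                f"no localisation within {search_radius_nm} nm of fiducial seed "
                f"{s_i} at {tuple(seed)}; nearest candidates at {np.round(nearest, 1)} nm"
            )
    samp = pd.DataFrame(samples, columns=["frame", "dx", "dy"])
    per_frame = samp.groupby("frame")[["dx", "dy"]].mean()

    f_min, f_max = int(frames[0]), int(frames[-1])
    knots = list(range(f_min, f_max, knot_spacing)) + [f_max]
    knots = sorted(set(knots))
    half = knot_spacing / 2
    kdx, kdy = [], []
    pf = per_frame.reset_index()
    for k in knots:
        sel = pf[(pf["frame"] >= k - half) & (pf["frame"] <= k + half)]
        if len(sel) == 0:
            kdx.append(np.nan)
            kdy.append(np.nan)
        elif len(sel) == 1:
            kdx.append(float(sel["dx"].iloc[0]))
            kdy.append(float(sel["dy"].iloc[0]))
        else:
            # local linear fit evaluated at the knot: unbiased at the
            # movie edges, where the averaging span is one-sided
            f = sel["frame"].to_numpy(dtype=float)
            kdx.append(float(np.polyval(np.polyfit(f, sel["dx"], 1), k)))
            kdy.append(float(np.polyval(np.polyfit(f, sel["dy"], 1), k)))
    kdx = pd.Series(kdx).interpolate(limit_direction="both").to_numpy()
    kdy = pd.Series(kdy).interpolate(limit_direction="both").to_numpy()
    knots_arr = np.asarray(knots, dtype=float)
    # anchor displacement at frame 0 to zero
    dx0 = np.interp(0.0, knots_arr, kdx)
    dy0 = np.interp(0.0, knots_arr, kdy)
    if knots_arr[0] > 0:
        knots_arr = np.r_[0.0, knots_arr]
        kdx = np.r_[dx0, kdx]
        kdy = np.r_[dy0, kdy]
    return DriftTrajectory(knots_arr, kdx - dx0, kdy - dy0)


def apply_drift_correction(table: pd.DataFrame, drift: DriftTrajectory) -> pd.DataFrame:
    """Subtract the interpolated drift displacement from every record."""
    lo, hi = drift.frame_span
    f = table["frame"].to_numpy()
    if len(f) and (f.min() < lo or f.max() > hi):
        raise ValueError(
            f"table frames [{f.min()}, {f.max()}] outside drift domain [{lo}, {hi}]"
        )
    dx, dy = drift.displacement(f)
    out = table.copy()
    out["x_nm"] = out["x_nm"] - dx
    out["y_nm"] = out["y_nm"] - dy
    return out
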