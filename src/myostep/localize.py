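"""Quantum-dot localization and tracking for TIRF motility movies.

Spot candidates are local maxima above a robust background threshold;
each is refined by a symmetric 2-D Gaussian least-squares fit of its
intensity profile (the point-spread function of a sub-diffraction
emitter), giving sub-pixel centers.  Fits are linked frame-to-frame by
greedy nearest-neighbor association into trajectories, and localization
precision is estimated as the pooled standard deviation of immobile
spots.

Pixel convention: pixel centers at integer coordinates, origin at the
top-left pixel center, 0-based; (x, y) = (column, row).  Conversion to
nm multiplies by the pixel size (91 nm by default in this package's
simulated geometry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "Roi",
    "SpotFit",
    "Trajectory",
    "DriftError",
    "detect_spots",
    "fit_gaussian2d",
    "fit_frame",
    "link_trajectories",
    "localization_precision",
]

DEFAULT_PIXEL_SIZE = 91.0  # nm


class DriftError(ValueError):
    """Raised when a spot meant to be immobile shows a significant trend."""


@dataclass(frozen=True)
class Roi:
    """Square region of interest around a candidate spot."""

    data: np.ndarray  # 2-D intensity patch
    row0: int  # absolute row of patch[0, 0]
    col0: int


@dataclass(frozen=True)
class SpotFit:
    """Converged symmetric-Gaussian PSF fit of one spot.

    Centers are absolute sub-pixel coordinates (x = column, y = row);
    ``sigma`` is the PSF width in pixels; ``residual`` is the RMS fit
    residual normalized by the amplitude.
    """

    x: float
    y: float
    sigma: float
    amplitude: float
    offset: float
    residual: float
    frame: int = 0


@dataclass
class Trajectory:
    """Time-stamped 2-D positions of one tracked spot, in nm."""

    frames: np.ndarray
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    precision: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("frames/times/x/y must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frames, "time_s": self.times, "x_nm": self.x, "y_nm": self.y}
        )


# ---------------------------------------------------------------------------
# detection and fitting
# ---------------------------------------------------------------------------

def detect_spots(
    frame: np.ndarray,
    k: float = 5.0,
    psf_sigma_px: float = 1.4,
    roi_half: int | None = None,
) -> list[Roi]:
    """Find candidate emitters as local maxima above background.

    Threshold is ``median + k * sigma_bg`` with a MAD-based robust
    background sigma; one ROI per maximum, with half-width at least
    three PSF sigmas so the Gaussian tail is covered.
    """
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        raise ValueError("empty frame")
    info = np.iinfo(frame.dtype) if np.issubdtype(frame.dtype, np.integer) else None
    if info is not None and np.any(frame >= info.max):
        warnings.warn("saturated pixels in frame; localization may be biased")
    med = float(np.median(img))
    sigma_bg = 1.4826 * float(np.median(np.abs(img - med)))
    threshold = med + k * sigma_bg
    if roi_half is None:
        roi_half = max(int(np.ceil(3.0 * psf_sigma_px)), 3)
    footprint = ndimage.maximum_filter(img, size=2 * roi_half + 1, mode="nearest")
    peaks = (img == footprint) & (img > threshold)
    coords = list(zip(*np.nonzero(peaks)))
    # ties on a plateau mark the same emitter twice: keep one per neighborhood
    accepted: list[tuple[int, int]] = []
    for r, c in sorted(coords, key=lambda rc: -img[rc]):
        if all(max(abs(r - r2), abs(c - c2)) > roi_half for r2, c2 in accepted):
            accepted.append((r, c))
    rois: list[Roi] = []
    for r, c in sorted(accepted):
        r0 = max(int(r) - roi_half, 0)
        c0 = max(int(c) - roi_half, 0)
        r1 = min(int(r) + roi_half + 1, img.shape[0])
        c1 = min(int(c) + roi_half + 1, img.shape[1])
        rois.append(Roi(img[r0:r1, c0:c1], r0, c0))
    return rois


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2)) + offset


def fit_gaussian2d(roi: Roi, frame_index: int = 0) -> SpotFit | None:
    """Least-squares symmetric 2-D Gaussian fit of one ROI.

    Returns ``None`` for singular/non-converged fits or when the fitted
    center falls outside the ROI (rejected spot).
    """
    patch = roi.data
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    offset0 = float(patch.min())
    amp0 = float(patch.max()) - offset0
    if amp0 <= 0:
        return None
    total = (patch - offset0).sum()
    x0 = float(((patch - offset0) * xx).sum() / total) if total > 0 else nx / 2
    y0 = float(((patch - offset0) * yy).sum() / total) if total > 0 else ny / 2
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            patch.ravel(),
            p0=[amp0, x0, y0, 1.3, offset0],
            maxfev=5000,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return None
    amp, cx, cy, sigma, offset = popt
    sigma = abs(float(sigma))
    if amp <= 0 or sigma <= 0:
        return None
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        return None
    resid = patch.ravel() - _gauss2d((xx.ravel(), yy.ravel()), *popt)
    return SpotFit(
        x=float(cx + roi.col0),
        y=float(cy + roi.row0),
        sigma=sigma,
        amplitude=float(amp),
        offset=float(offset),
        residual=float(np.sqrt(np.mean(resid**2)) / amp),
        frame=frame_index,
    )


def fit_frame(frame: np.ndarray, frame_index: int = 0, **detect_kwargs) -> list[SpotFit]:
    """Detect and fit all spots in one frame."""
    fits = []
    for roi in detect_spots(frame, **detect_kwargs):
        fit = fit_gaussian2d(roi, frame_index)
        if fit is not None:
            fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_trajectories(
    fits_per_frame: dict[int, list[SpotFit]],
    max_jump: float,
    min_frames: int = 10,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = 0.1,
) -> tuple[list[Trajectory], int]:
    """Greedy nearest-neighbor linking of per-frame fits.

    A fit joins the nearest active track within ``max_jump`` nm (tie on
    distance broken by lower fit residual); unmatched fits start new
    tracks.  Tracks shorter than ``min_frames`` are discarded and
    counted.  Returns (trajectories, n_discarded).
    """
    active: list[dict] = []
    finished: list[dict] = []
    for frame in sorted(fits_per_frame):
        fits = sorted(fits_per_frame[frame], key=lambda f: f.residual)
        taken = set()
        next_active = []
        # pair each active track with its best candidate
        for tr in active:
            best, best_d = None, np.inf
            for i, f in enumerate(fits):
                if i in taken:
                    continue
                d = np.hypot(f.x - tr["x"][-1] / pixel_size,
                             f.y - tr["y"][-1] / pixel_size) * pixel_size
                if d < best_d - 1e-12:
                    best, best_d = i, d
            if best is not None and best_d <= max_jump:
                taken.add(best)
                f = fits[best]
                tr["frames"].append(frame)
                tr["x"].append(f.x * pixel_size)
                tr["y"].append(f.y * pixel_size)
                next_active.append(tr)
            else:
                finished.append(tr)
        for i, f in enumerate(fits):
            if i not in taken:
                next_active.append({
                    "frames": [frame],
                    "x": [f.x * pixel_size],
                    "y": [f.y * pixel_size],
                })
        active = next_active
    finished.extend(active)

    trajectories, discarded = [], 0
    for tr in finished:
        if len(tr["frames"]) < min_frames:
            discarded += 1
            continue
        frames = np.array(tr["frames"])
        trajectories.append(
            Trajectory(frames, frames * frame_interval, tr["x"], tr["y"])
        )
    return trajectories, discarded


# ---------------------------------------------------------------------------
# precision
# ---------------------------------------------------------------------------

def localization_precision(traj: Trajectory, min_frames: int = 20) -> float:
    """Pooled per-axis standard deviation of an immobile spot (nm).

    Requires at least ``min_frames`` frames.  A linear trend larger than
    twice the residual noise over the trajectory duration indicates the
    spot is not immobile and raises :class:`DriftError`.
    """
    if len(traj) < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {len(traj)}")
    t = traj.times - traj.times.mean()
    resid_vars, drift = [], 0.0
    for axis in (traj.x, traj.y):
        slope, intercept = np.polyfit(t, axis, 1)
        resid = axis - (slope * t + intercept)
        resid_vars.append(np.var(resid, ddof=2))
        drift = max(drift, abs(slope) * traj.duration)
    noise = float(np.sqrt(np.mean(resid_vars)))
    if drift > 2.0 * noise + 1e-9:
        raise DriftError(
            f"spot drifts {drift:.1f} nm over the trajectory "
            f"(> 2 x {noise:.1f} nm noise); not immobile")
    var = np.var(traj.x, ddof=1) + np.var(traj.y, ddof=1)
    return float(np.sqrt(var / 2.0))
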