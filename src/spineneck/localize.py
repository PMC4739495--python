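"""Single-molecule localization: detection, sub-pixel Gaussian fitting,
fiducial drift correction, pointing accuracy and super-resolution rendering.

Coordinate conventions: positions are in nm, origin at the center of the
top-left pixel, x rightward (columns), y downward (rows); frame indices are
0-based.  Localization tables are pandas DataFrames with columns
``frame, x_nm, y_nm, sigma_nm, intensity, channel, valid``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from skimage.feature import peak_local_max

__all__ = [
    "Localization", "DriftTrace", "PointingAccuracy", "SuperResImage",
    "detect_spots", "fit_gaussian_2d", "localize_stack", "correct_drift",
    "estimate_pointing_accuracy", "cluster_detections", "render_superres",
]

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "intensity", "channel", "valid"]


@dataclass
class Localization:
    """One fitted single-molecule detection."""

    frame: int
    x_nm: float
    y_nm: float
    sigma_nm: float
    intensity: float
    channel: str = "other"
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if not (np.isfinite(self.x_nm) and np.isfinite(self.y_nm)):
                raise ValueError("valid localization requires finite coordinates")
            if self.frame < 0:
                raise ValueError("frame must be >= 0")
            if not self.sigma_nm > 0:
                raise ValueError("valid localization requires fit_sigma > 0")


@dataclass
class DriftTrace:
    """Per-frame rigid translation (dx, dy in nm), zero at the reference frame."""

    frames: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    residual_rms_nm: float
    n_fiducials: int


@dataclass
class PointingAccuracy:
    """Per-axis SD of repeated localizations of one fluorophore."""

    sigma_x: float
    sigma_y: float
    n_detections: int


@dataclass
class SuperResImage:
    """Rendered image with its physical pixel size and origin (nm)."""

    data: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)   # (x, y) of pixel [0, 0] center

    def nm_to_px(self, x_nm: np.ndarray, y_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return ((np.asarray(x_nm) - self.origin_nm[0]) / self.pixel_nm,
                (np.asarray(y_nm) - self.origin_nm[1]) / self.pixel_nm)


# --------------------------------------------------------------------------
# detection and fitting
# --------------------------------------------------------------------------

def detect_spots(image: np.ndarray, threshold: float | None = None,
                 smooth_sigma: float = 1.0, min_separation: int = 3,
                 k_sigma: float = 5.0) -> np.ndarray:
    """Candidate spot pixels: local maxima of the smoothed frame above threshold.

    If ``threshold`` is None it is set to median + k_sigma * robust SD (MAD)
    of the smoothed image.  Returns an (n, 2) integer array of (row, col)
    candidates, no two closer than ``min_separation`` pixels.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("detect_spots expects a 2D image")
    sm = ndimage.gaussian_filter(image, smooth_sigma)
    if threshold is None:
        med = np.median(sm)
        mad = np.median(np.abs(sm - med)) * 1.4826
        threshold = med + k_sigma * max(mad, 1e-12)
    peaks = peak_local_max(sm, min_distance=min_separation,
                           threshold_abs=threshold, exclude_border=False)
    return peaks


def _gauss2d_residuals(p, cols, rows, data):
    amp, x0, y0, sigma, offset = p
    model = offset + amp * np.exp(-((cols - x0) ** 2 + (rows - y0) ** 2) / (2 * sigma ** 2))
    return (model - data).ravel()


def fit_gaussian_2d(image: np.ndarray, candidate: tuple[int, int],
                    window: int = 7, pixel_nm: float = 107.0,
                    psf_sigma_px: float = 1.3, frame: int = 0,
                    channel: str = "other",
                    sigma_bounds: tuple[float, float] = (0.5, 4.0)) -> Localization:
    """Least-squares 2D Gaussian fit around a candidate pixel.

    Fits amplitude, sub-pixel center, isotropic sigma and offset in a
    ``window`` x ``window`` region; converts the center to nm.  The result is
    marked invalid (rather than raising) when the window is flat, the fit
    diverges, or the fitted sigma falls outside
    ``sigma_bounds`` x ``psf_sigma_px``.
    """
    image = np.asarray(image, float)
    half = window // 2
    r, c = int(candidate[0]), int(candidate[1])
    if r - half < 0 or c - half < 0 or r + half >= image.shape[0] or c + half >= image.shape[1]:
        raise ValueError("fit window extends outside the image")
    sub = image[r - half:r + half + 1, c - half:c + half + 1]
    rows, cols = np.mgrid[r - half:r + half + 1, c - half:c + half + 1]

    invalid = Localization(frame=frame, x_nm=np.nan, y_nm=np.nan, sigma_nm=np.nan,
                           intensity=np.nan, channel=channel, valid=False)
    span = sub.max() - sub.min()
    if span <= 0:
        return invalid
    p0 = [span, float(c), float(r), psf_sigma_px, float(sub.min())]
    try:
        res = least_squares(_gauss2d_residuals, p0, args=(cols, rows, sub),
                            bounds=([0, c - half, r - half, 0.1, -np.inf],
                                    [np.inf, c + half, r + half, 10 * psf_sigma_px, np.inf]),
                            max_nfev=500)
    except Exception:
        return invalid
    amp, x0, y0, sigma, offset = res.x
    lo, hi = sigma_bounds[0] * psf_sigma_px, sigma_bounds[1] * psf_sigma_px
    if not res.success or not (lo <= sigma <= hi) or amp <= 0:
        return invalid
    return Localization(frame=frame, x_nm=x0 * pixel_nm, y_nm=y0 * pixel_nm,
                        sigma_nm=sigma * pixel_nm, intensity=float(amp),
                        channel=channel, valid=True)


def localize_stack(stack: np.ndarray, pixel_nm: float = 107.0,
                   psf_sigma_px: float = 1.3, window: int = 7,
                   channel: str = "other", **detect_kwargs) -> pd.DataFrame:
    """Detect and fit spots in every frame of a stack; returns a table."""
    rows = []
    half = window // 2
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    for i, frame in enumerate(stack):
        for (r, c) in detect_spots(frame, **detect_kwargs):
            if (r < half or c < half or r >= frame.shape[0] - half
                    or c >= frame.shape[1] - half):
                continue
            loc = fit_gaussian_2d(frame, (r, c), window=window, pixel_nm=pixel_nm,
                                  psf_sigma_px=psf_sigma_px, frame=i, channel=channel)
            if loc.valid:
                rows.append(loc.__dict__)
    if not rows:
        return pd.DataFrame(columns=LOC_COLUMNS)
    return pd.DataFrame(rows)[LOC_COLUMNS]


# --------------------------------------------------------------------------
# drift correction
# --------------------------------------------------------------------------

def correct_drift(locs: pd.DataFrame, fiducials: pd.DataFrame,
                  n_frames: int | None = None, smooth_window: int = 101,
                  min_coverage: float = 0.9) -> tuple[pd.DataFrame, DriftTrace]:
    """Subtract the mean fiducial displacement trace from all localizations.

    ``fiducials`` has columns (fid_id, frame, x_nm, y_nm).  Each fiducial's
    displacement from its reference-frame position is averaged across
    fiducials, interpolated across gaps, and smoothed with a local-linear
    (Savitzky-Golay, polyorder 1) filter over ``smooth_window`` frames —
    the edge-unbiased form of a moving average.  Requires at least one
    fiducial present in >= ``min_coverage`` of frames.
    """
    if n_frames is None:
        n_frames = int(max(locs["frame"].max() if len(locs) else 0,
                           fiducials["frame"].max())) + 1
    frames = np.arange(n_frames)
    traces = []
    best_cov = 0.0
    for _, g in fiducials.groupby("fid_id"):
        g = g.sort_values("frame")
        cov = len(g) / n_frames
        best_cov = max(best_cov, cov)
        fx = np.interp(frames, g["frame"], g["x_nm"])
        fy = np.interp(frames, g["frame"], g["y_nm"])
        traces.append(np.stack([fx - fx[0], fy - fy[0]], axis=1))
    if not traces or best_cov < min_coverage:
        raise ValueError(
            f"insufficient fiducial coverage: best fiducial present in "
            f"{best_cov:.0%} of {n_frames} frames (need >= {min_coverage:.0%})")
    drift = np.mean(traces, axis=0)   # (n_frames, 2), zero at frame 0
    if smooth_window > 2 and n_frames > 4:
        win = min(smooth_window, n_frames if n_frames % 2 else n_frames - 1)
        drift = np.stack([savgol_filter(drift[:, 0], win, 1, mode="interp"),
                          savgol_filter(drift[:, 1], win, 1, mode="interp")], axis=1)
    drift -= drift[0]

    corrected = locs.copy()
    if len(locs):
        idx = locs["frame"].to_numpy().astype(int)
        corrected["x_nm"] = locs["x_nm"].to_numpy() - drift[idx, 0]
        corrected["y_nm"] = locs["y_nm"].to_numpy() - drift[idx, 1]

    # residual: fiducial scatter about its own mean after correction
    resid = []
    for _, g in fiducials.groupby("fid_id"):
        idx = g["frame"].to_numpy().astype(int)
        cx = g["x_nm"].to_numpy() - drift[idx, 0]
        cy = g["y_nm"].to_numpy() - drift[idx, 1]
        resid.append(np.concatenate([cx - cx.mean(), cy - cy.mean()]))
    rms = float(np.sqrt(np.mean(np.concatenate(resid) ** 2)))
    trace = DriftTrace(frames=frames, dx=drift[:, 0], dy=drift[:, 1],
                       residual_rms_nm=rms, n_fiducials=fiducials["fid_id"].nunique())
    return corrected, trace


# --------------------------------------------------------------------------
# pointing accuracy
# --------------------------------------------------------------------------

def cluster_detections(locs: pd.DataFrame, seed_xy: tuple[float, float] | None = None,
                       radius_nm: float = 50.0) -> pd.DataFrame:
    """Detections within ``radius_nm`` of a seed point (default: densest spot)."""
    if seed_xy is None:
        seed_xy = (locs["x_nm"].median(), locs["y_nm"].median())
    d = np.hypot(locs["x_nm"] - seed_xy[0], locs["y_nm"] - seed_xy[1])
    return locs[d <= radius_nm]


def estimate_pointing_accuracy(locs: pd.DataFrame) -> PointingAccuracy:
    """Per-axis sample SD of one isolated fluorophore's repeated detections."""
    n = len(locs)
    if n < 5:
        raise ValueError(f"need >= 5 detections to estimate pointing accuracy, got {n}")
    return PointingAccuracy(sigma_x=float(locs["x_nm"].std(ddof=1)),
                            sigma_y=float(locs["y_nm"].std(ddof=1)),
                            n_detections=n)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_superres(locs: pd.DataFrame, sigma_render: float = 10.0,
                    pixel_out: float = 5.0,
                    extent: tuple[float, float, float, float] | None = None,
                    ) -> SuperResImage:
    """Pointillist rendering: each detection becomes a unit-integral Gaussian.

    Gaussians of SD ``sigma_render`` nm are integrated exactly over output
    pixels of ``pixel_out`` nm, so the image of n detections sums to ~n
    (up to truncation beyond 5 sigma).  ``extent`` is (x_min, x_max, y_min,
    y_max) in nm; by default it covers the detections with a 5-sigma margin.
    """
    from scipy.special import erf

    if sigma_render <= 0:
        raise ValueError("sigma_render must be > 0")
    if pixel_out > sigma_render:
        raise ValueError("pixel_out must be <= sigma_render for faithful rendering")
    if extent is None:
        if len(locs) == 0:
            extent = (0.0, pixel_out, 0.0, pixel_out)
        else:
            m = 5 * sigma_render
            extent = (locs["x_nm"].min() - m, locs["x_nm"].max() + m,
                      locs["y_nm"].min() - m, locs["y_nm"].max() + m)
    x0, x1, y0, y1 = extent
    w = max(int(np.ceil((x1 - x0) / pixel_out)), 1)
    h = max(int(np.ceil((y1 - y0) / pixel_out)), 1)
    img = np.zeros((h, w))
    if len(locs) == 0:
        return SuperResImage(img, pixel_out, (x0, y0))

    s2 = sigma_render * np.sqrt(2.0)
    half = int(np.ceil(5 * sigma_render / pixel_out)) + 1
    xs = locs["x_nm"].to_numpy()
    ys = locs["y_nm"].to_numpy()
    for x, y in zip(xs, ys):
        cx = (x - x0) / pixel_out
        cy = (y - y0) / pixel_out
        c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        # pixel j covers [x0 + j*px - px/2, x0 + j*px + px/2] around its center
        ex = 0.5 * (erf(((cols + 0.5) * pixel_out + x0 - x) / s2)
                    - erf(((cols - 0.5) * pixel_out + x0 - x) / s2))
        ey = 0.5 * (erf(((rows + 0.5) * pixel_out + y0 - y) / s2)
                    - erf(((rows - 0.5) * pixel_out + y0 - y) / s2))
        img[r0:r1, c0:c1] += np.outer(ey, ex)
    return SuperResImage(img, pixel_out, (x0, y0))


def align_channels(fiducials_a: pd.DataFrame, fiducials_b: pd.DataFrame
                   ) -> tuple[float, float]:
    """Rigid translation (dx, dy in nm) mapping channel B onto channel A,
    computed from matched fiducial centroids."""
    ax, ay = fiducials_a["x_nm"].mean(), fiducials_a["y_nm"].mean()
    bx, by = fiducials_b["x_nm"].mean(), fiducials_b["y_nm"].mean()
    return float(ax - bx), float(ay - by)
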