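"""Domain-width (FWHM) measurement across the spine neck.

Two routes mirror the two ways super-resolution data are summarized:
``extract_transverse_profile`` + ``fwhm_of_profile`` operate on rendered
images (intensity profile perpendicular to the neck axis, averaged over a
band along the axis), while ``detection_histogram_fwhm`` bins the raw
single-molecule detections falling inside a 200 nm segment across the neck.
``domain_gap`` converts an outer/inner width pair into the radial gap
between the two domains, (outer - inner) / 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .localize import SuperResImage

__all__ = ["NeckAxisROI", "FwhmResult", "extract_transverse_profile",
           "fwhm_of_profile", "detection_histogram_fwhm", "domain_gap"]


@dataclass
class NeckAxisROI:
    """Neck axis segment with the averaging band and detection-segment length.

    ``band_width`` (nm) is the extent along the axis over which the rendered
    profile is averaged; ``segment_length`` (nm, default 200) is the width of
    the across-neck segment used for detection histograms.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    band_width: float = 100.0
    segment_length: float = 200.0

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ValueError("axis endpoints must be distinct")
        if self.band_width <= 0:
            raise ValueError("band_width must be > 0")

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.p0, float) + np.asarray(self.p1, float)) / 2.0

    @property
    def axis_unit(self) -> np.ndarray:
        v = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        return v / np.linalg.norm(v)

    @property
    def normal_unit(self) -> np.ndarray:
        ux, uy = self.axis_unit
        return np.array([-uy, ux])

    def to_json(self) -> str:
        return json.dumps({"axis": [list(self.p0), list(self.p1)],
                           "band_nm": self.band_width,
                           "segment_nm": self.segment_length})

    @classmethod
    def from_json(cls, text: str) -> "NeckAxisROI":
        d = json.loads(text)
        (x0, y0), (x1, y1) = d["axis"]
        return cls((x0, y0), (x1, y1), d.get("band_nm", 100.0),
                   d.get("segment_nm", 200.0))


@dataclass
class FwhmResult:
    fwhm_nm: float
    method: str                      # rendered_profile | detection_histogram
    peak_position_nm: float
    background: float
    channel: str = ""
    n_detections: int | None = None
    defined: bool = True
    multi_peak: bool = False


def extract_transverse_profile(image: SuperResImage, roi: NeckAxisROI,
                               transverse_extent: float = 300.0,
                               step_nm: float | None = None,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity perpendicular to the neck axis.

    Samples the image (bilinear interpolation) on a grid of transverse
    positions t in [-transverse_extent, +transverse_extent] (0 on the axis)
    by along-axis offsets spanning ``roi.band_width`` around the midpoint,
    and averages along the axis.  Returns (positions_nm, intensities).
    """
    if step_nm is None:
        step_nm = image.pixel_nm
    t = np.arange(-transverse_extent, transverse_extent + step_nm / 2, step_nm)
    n_band = max(int(round(roi.band_width / step_nm)), 1)
    a = (np.arange(n_band) - (n_band - 1) / 2) * step_nm
    mid, u, nvec = roi.midpoint, roi.axis_unit, roi.normal_unit
    pts = (mid[None, None, :] + t[:, None, None] * nvec[None, None, :]
           + a[None, :, None] * u[None, None, :])          # (nt, na, 2) nm
    px, py = image.nm_to_px(pts[..., 0], pts[..., 1])
    h, w = image.data.shape
    # the ROI band itself (t = 0 samples) must lie inside the image;
    # transverse samples beyond the rendered extent read as zero background
    axis_row = len(t) // 2
    ax_px, ax_py = px[axis_row], py[axis_row]
    if (ax_px.min() < -0.5 or ax_px.max() > w - 0.5 or ax_py.min() < -0.5
            or ax_py.max() > h - 0.5):
        raise ValueError("ROI lies outside the image")
    vals = ndimage.map_coordinates(image.data, [py.ravel(), px.ravel()],
                                   order=1, mode="constant", cval=0.0
                                   ).reshape(px.shape)
    return t, vals.mean(axis=1)


def fwhm_of_profile(positions: np.ndarray, values: np.ndarray,
                    channel: str = "", method: str = "rendered_profile",
                    smooth_sigma_nm: float = 0.0,
                    background_fraction: float = 0.2) -> FwhmResult:
    """FWHM of a peaked profile with tail-based background subtraction.

    The background is the median of the outer ``background_fraction`` of
    positions (split between the two tails); half-maximum crossings are
    located by linear interpolation, scanning inward from each end so that
    multi-peaked profiles (e.g. the two edge peaks of a membrane shell)
    yield the width of the envelope.  Profiles with more than one local
    maximum above half-max are flagged ``multi_peak``; an optional Gaussian
    pre-smoothing (``smooth_sigma_nm``) regularises them.
    """
    positions = np.asarray(positions, float)
    values = np.asarray(values, float)
    if len(positions) < 5:
        raise ValueError("profile too short")
    order = np.argsort(positions)
    positions, values = positions[order], values[order]
    if smooth_sigma_nm > 0:
        step = np.median(np.diff(positions))
        values = ndimage.gaussian_filter1d(values, smooth_sigma_nm / step)

    n_tail = max(int(np.ceil(len(positions) * background_fraction / 2)), 1)
    background = float(np.median(np.r_[values[:n_tail], values[-n_tail:]]))
    peak_idx = int(np.argmax(values))
    peak = values[peak_idx]
    half = background + (peak - background) / 2.0

    undefined = FwhmResult(fwhm_nm=np.nan, method=method, peak_position_nm=np.nan,
                           background=background, channel=channel, defined=False)
    if peak <= background:
        return undefined

    above = values >= half
    # interior local maxima above half-max
    interior = values[1:-1]
    n_peaks = int(np.sum((interior > values[:-2]) & (interior >= values[2:])
                         & (interior >= half)))
    multi_peak = n_peaks > 1

    # scan inward from each end for the outermost crossings
    def crossing(idx_range):
        for i in idx_range:
            if above[i]:
                j = i - 1 if idx_range.step == 1 else i + 1
                if j < 0 or j >= len(values):
                    return None  # profile starts above half: no crossing
                x0, x1 = positions[j], positions[i]
                v0, v1 = values[j], values[i]
                return x0 + (half - v0) * (x1 - x0) / (v1 - v0)
        return None

    left = crossing(range(0, peak_idx + 1, 1))
    right = crossing(range(len(values) - 1, peak_idx - 1, -1))
    if left is None or right is None:
        return undefined
    return FwhmResult(fwhm_nm=float(right - left), method=method,
                      peak_position_nm=float(positions[peak_idx]),
                      background=background, channel=channel,
                      multi_peak=multi_peak)


def detection_histogram_fwhm(locs: pd.DataFrame, roi: NeckAxisROI,
                             bin_nm: float = 10.0, min_detections: int = 50,
                             channel: str = "", **fwhm_kwargs) -> FwhmResult:
    """FWHM of the transverse detection histogram in a segment across the neck.

    Detections whose along-axis coordinate lies within ``roi.segment_length``
    centered on the ROI midpoint are projected onto the transverse direction,
    binned at ``bin_nm``, and the binned counts are measured like a rendered
    profile.
    """
    mid, u, nvec = roi.midpoint, roi.axis_unit, roi.normal_unit
    rel = np.stack([locs["x_nm"].to_numpy() - mid[0],
                    locs["y_nm"].to_numpy() - mid[1]], axis=1)
    axial = rel @ u
    transverse = rel @ nvec
    keep = np.abs(axial) <= roi.segment_length / 2.0
    tsel = transverse[keep]
    if len(tsel) < min_detections:
        raise ValueError(f"only {len(tsel)} detections inside the "
                         f"{roi.segment_length:.0f} nm segment (need >= {min_detections})")
    lo = np.floor(tsel.min() / bin_nm) * bin_nm - 4 * bin_nm
    hi = np.ceil(tsel.max() / bin_nm) * bin_nm + 4 * bin_nm
    edges = np.arange(lo, hi + bin_nm / 2, bin_nm)
    counts, _ = np.histogram(tsel, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    res = fwhm_of_profile(centers, counts.astype(float), channel=channel,
                          method="detection_histogram", **fwhm_kwargs)
    res.n_detections = int(len(tsel))
    return res


def domain_gap(outer_fwhm: float, inner_fwhm: float) -> float:
    """Radial gap between a nested inner domain and an outer one.

    With both widths measured across the same axis, the inner domain leaves
    (outer - inner) / 2 of clearance on each side.
    """
    if outer_fwhm < inner_fwhm:
        raise ValueError(f"outer FWHM ({outer_fwhm}) must be >= inner ({inner_fwhm})")
    return (outer_fwhm - inner_fwhm) / 2.0
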