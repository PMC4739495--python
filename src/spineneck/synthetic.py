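"""Synthetic imaging data with known ground truth for the spine-neck pipeline.

The generators emulate the study conditions this package analyses:

* quantum-dot trajectories diffusing on the membrane of a cylindrical spine
  neck (~100-200 nm outer diameter), 12 ms frame interval, 10-20 nm
  localization noise, with a slower diffusivity inside the synaptopodin (SP)
  segment of the neck;
* STORM/PALM detection clouds for the three nested domains of the neck — an
  inner SP rod (66 nm default diameter), the F-actin-filled core (105 nm) and
  the membrane shell (195 nm) — with per-axis pointing accuracy of 12-14 nm;
* raw single-molecule movies (integrated-Gaussian PSF + Poisson noise);
* widefield dendrite images with punctate SP clusters for wavelet
  segmentation;
* FRAP recovery curves with two time constants, acquisition photobleaching
  and an optional rising baseline (latrunculin-A-like recruitment).

Every generator takes an explicit seed (or a seeded config) and is
bit-reproducible; no global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .frap import FrapSeries

__all__ = [
    "NeckGeometry", "SimulationConfig", "GroundTruth",
    "SP_AREA", "NO_SP_AREA", "DENDRITE",
    "simulate_trajectories_on_cylinder", "simulate_detection_cloud",
    "simulate_spot_movie", "simulate_widefield_image", "simulate_frap_curve",
]

# Region labels used throughout the pipeline.
SP_AREA = "SP area"
NO_SP_AREA = "no SP area"
DENDRITE = "dendrite"

#: species -> imaging channel, matching the probes used for each domain
SPECIES_CHANNEL = {"SP": "dendra", "actin": "A647", "membrane": "other"}


@dataclass(frozen=True)
class NeckGeometry:
    """Idealised spine neck: three coaxial domains along a 2D axis segment.

    Diameters are the true (3D) domain diameters in nm; the projected widths
    measured by the pipeline are related to them through the projection
    geometry (e.g. a filled cylinder of diameter d projects to a chord-length
    density with FWHM d*sqrt(3)/2, before localization blur).
    """

    axis_start: tuple[float, float] = (0.0, 0.0)      # nm, camera plane
    axis_end: tuple[float, float] = (1000.0, 0.0)     # nm
    outer_diameter: float = 195.0                     # membrane shell, nm
    actin_diameter: float = 105.0                     # filled F-actin core, nm
    sp_diameter: float = 66.0                         # filled SP rod, nm
    sp_segment: tuple[float, float] | None = (300.0, 700.0)  # along-axis, nm

    def __post_init__(self) -> None:
        for d in (self.outer_diameter, self.actin_diameter, self.sp_diameter):
            if not np.isfinite(d) or d <= 0:
                raise ValueError(f"diameters must be positive and finite, got {d}")
        if not self.sp_diameter <= self.actin_diameter <= self.outer_diameter:
            raise ValueError("require sp_diameter <= actin_diameter <= outer_diameter")
        if self.length <= 0:
            raise ValueError("axis length must be positive")
        if self.sp_segment is not None:
            lo, hi = self.sp_segment
            if not (0.0 <= lo < hi <= self.length):
                raise ValueError("sp_segment must be a sub-interval of [0, axis length]")

    @property
    def length(self) -> float:
        return float(np.hypot(self.axis_end[0] - self.axis_start[0],
                              self.axis_end[1] - self.axis_start[1]))

    @property
    def sp_present(self) -> bool:
        return self.sp_segment is not None

    @property
    def axis_unit(self) -> np.ndarray:
        v = np.subtract(self.axis_end, self.axis_start)
        return v / np.linalg.norm(v)

    @property
    def normal_unit(self) -> np.ndarray:
        ux, uy = self.axis_unit
        return np.array([-uy, ux])

    def region_of(self, z: np.ndarray) -> np.ndarray:
        """Region label for along-axis coordinates z (nm)."""
        z = np.asarray(z, float)
        labels = np.full(z.shape, NO_SP_AREA, dtype=object)
        if self.sp_present:
            lo, hi = self.sp_segment
            labels[(z >= lo) & (z <= hi)] = SP_AREA
        return labels

    def to_camera(self, z: np.ndarray, transverse: np.ndarray) -> np.ndarray:
        """Map (along-axis, transverse) nm coordinates to camera-plane (x, y)."""
        p = (np.asarray(self.axis_start)[None, :]
             + np.asarray(z, float)[:, None] * self.axis_unit[None, :]
             + np.asarray(transverse, float)[:, None] * self.normal_unit[None, :])
        return p


@dataclass
class SimulationConfig:
    """Imaging/simulation parameters shared by the generators."""

    frame_interval: float = 0.012     # s, streamed QD recording
    n_frames: int = 100
    D_map: dict[str, float] = field(default_factory=lambda: {SP_AREA: 0.025,
                                                             NO_SP_AREA: 0.05})
    loc_noise_sigma: float = 15.0     # nm, per axis
    pixel_size: float = 107.0         # nm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if any(d < 0 for d in self.D_map.values()):
            raise ValueError("diffusivities must be >= 0")


@dataclass
class GroundTruth:
    """Per-object truth accompanying each generator's output."""

    trajectories: pd.DataFrame | None = None   # traj_id, region, true_D, frac_in_region
    cloud: dict | None = None                  # species, true diameter, sigma_xy
    emitters: list[np.ndarray] | None = None   # per-frame true positions (px)
    clusters: pd.DataFrame | None = None       # widefield punctum positions/amplitudes
    frap: dict | None = None                   # true recovery parameters


# --------------------------------------------------------------------------
# trajectories on a cylindrical membrane
# --------------------------------------------------------------------------

def simulate_trajectories_on_cylinder(geom: NeckGeometry, cfg: SimulationConfig,
                                      n_traj: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Brownian trajectories on the (unwrapped) cylindrical neck membrane.

    Motion lives on the membrane surface, parameterised by the longitudinal
    coordinate z and the arc coordinate s = r*theta with r the membrane
    radius.  Per-frame steps are N(0, 2*D*dt) on each surface axis, with D
    chosen by the region containing the current z (sharp change at the SP
    segment edges).  Longitudinal motion is unbounded: the tube is taken to
    continue beyond the measured segment (into head and dendrite), so the
    neck ends impose no artificial reflecting confinement on the estimator.
    The camera sees the orthogonal projection (x along the axis,
    y = r*sin(theta)) plus isotropic Gaussian localization noise.

    Returns a tidy table (traj_id, frame, x_nm, y_nm) and per-trajectory
    ground truth (majority region, that region's true D, occupancy fraction).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    regions = set(np.unique(geom.region_of(np.linspace(0, geom.length, 64))))
    missing = regions - set(cfg.D_map)
    if missing:
        raise ValueError(f"D_map missing region(s): {sorted(missing)}")
    rng = np.random.default_rng(cfg.rng_seed)
    r = geom.outer_diameter / 2.0
    n = cfg.n_frames
    dt = cfg.frame_interval

    z = rng.uniform(0.0, geom.length, size=n_traj)
    theta = rng.uniform(0.0, 2 * np.pi, size=n_traj)
    zs = np.empty((n_traj, n))
    ths = np.empty((n_traj, n))
    zs[:, 0] = z
    ths[:, 0] = theta
    # step SD in nm: D um^2/s -> nm^2/s is 1e6 * D
    d_of = np.vectorize(lambda lab: cfg.D_map[lab])
    for i in range(1, n):
        lab = geom.region_of(zs[:, i - 1])
        sd = np.sqrt(2.0e6 * d_of(lab) * dt)
        step = rng.normal(0.0, 1.0, size=(n_traj, 2)) * sd[:, None]
        zs[:, i] = zs[:, i - 1] + step[:, 0]
        ths[:, i] = ths[:, i - 1] + step[:, 1] / r

    x = (np.asarray(geom.axis_start)[None, None, :]
         + zs[..., None] * geom.axis_unit[None, None, :]
         + (r * np.sin(ths))[..., None] * geom.normal_unit[None, None, :])
    if cfg.loc_noise_sigma > 0:
        x = x + rng.normal(0.0, cfg.loc_noise_sigma, size=x.shape)

    traj_id = np.repeat(np.arange(n_traj), n)
    frames = np.tile(np.arange(n), n_traj)
    table = pd.DataFrame({"traj_id": traj_id, "frame": frames,
                          "x_nm": x[..., 0].ravel(), "y_nm": x[..., 1].ravel()})

    labels = geom.region_of(zs.ravel()).reshape(n_traj, n)
    frac_sp = (labels == SP_AREA).mean(axis=1)
    major = np.where(frac_sp >= 0.5, SP_AREA, NO_SP_AREA)
    frac = np.where(frac_sp >= 0.5, frac_sp, 1.0 - frac_sp)
    truth = pd.DataFrame({
        "traj_id": np.arange(n_traj),
        "region": major,
        "true_D": [cfg.D_map[m] for m in major],
        "frac_in_region": frac,
    })
    return table, GroundTruth(trajectories=truth)


# --------------------------------------------------------------------------
# STORM/PALM detection clouds
# --------------------------------------------------------------------------

def simulate_detection_cloud(geom: NeckGeometry, species: str, n_detections: int,
                             sigma_xy: float, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Detection cloud for one labelled domain of the neck, projected to 2D.

    3D points are sampled uniformly in the species' domain — SP: filled rod of
    ``sp_diameter`` restricted to ``sp_segment``; actin: filled cylinder of
    ``actin_diameter`` over the whole axis; membrane: infinitely thin shell at
    ``outer_diameter`` — then orthogonally projected to the camera plane and
    perturbed by isotropic Gaussian localization error ``sigma_xy`` per axis.
    """
    if n_detections < 1:
        raise ValueError("n_detections must be >= 1")
    if species not in SPECIES_CHANNEL:
        raise ValueError(f"unknown species {species!r}; expected one of {sorted(SPECIES_CHANNEL)}")
    if species == "SP" and not geom.sp_present:
        raise ValueError("geometry has no SP segment; cannot simulate SP cloud")
    rng = np.random.default_rng(seed)

    if species == "SP":
        radius = geom.sp_diameter / 2.0
        z = rng.uniform(*geom.sp_segment, size=n_detections)
        diameter = geom.sp_diameter
    elif species == "actin":
        radius = geom.actin_diameter / 2.0
        z = rng.uniform(0.0, geom.length, size=n_detections)
        diameter = geom.actin_diameter
    else:  # membrane shell
        radius = geom.outer_diameter / 2.0
        z = rng.uniform(0.0, geom.length, size=n_detections)
        diameter = geom.outer_diameter

    phi = rng.uniform(0.0, 2 * np.pi, size=n_detections)
    if species == "membrane":
        transverse = radius * np.cos(phi)
    else:
        rr = radius * np.sqrt(rng.uniform(size=n_detections))
        transverse = rr * np.cos(phi)

    p = geom.to_camera(z, transverse)
    if sigma_xy > 0:
        p = p + rng.normal(0.0, sigma_xy, size=p.shape)
    table = pd.DataFrame({
        "frame": np.arange(n_detections),
        "x_nm": p[:, 0], "y_nm": p[:, 1],
        "channel": SPECIES_CHANNEL[species],
        "intensity": 1.0,
        "sigma_nm": float(sigma_xy),
    })
    truth = GroundTruth(cloud={"species": species, "true_diameter_nm": diameter,
                               "sigma_xy_nm": float(sigma_xy)})
    return table, truth


# --------------------------------------------------------------------------
# raw single-molecule movies
# --------------------------------------------------------------------------

def _integrated_gaussian(shape: tuple[int, int], pos: np.ndarray, sigma: float,
                         photons: float) -> np.ndarray:
    """Expected photon image of emitters: Gaussian PSF integrated over pixels."""
    h, w = shape
    img = np.zeros(shape, dtype=float)
    if len(pos) == 0:
        return img
    half = int(np.ceil(4 * sigma)) + 1
    s2 = sigma * np.sqrt(2.0)
    for (cx, cy) in np.atleast_2d(pos):  # pos columns: (x=col, y=row), px
        r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        fy = 0.5 * (erf((rows - cy + 0.5) / s2) - erf((rows - cy - 0.5) / s2))
        fx = 0.5 * (erf((cols - cx + 0.5) / s2) - erf((cols - cx - 0.5) / s2))
        img[r0:r1, c0:c1] += photons * np.outer(fy, fx)
    return img


def simulate_spot_movie(positions_per_frame: Sequence[np.ndarray],
                        psf_sigma: float, photon_count: float, background: float,
                        shape: tuple[int, int], seed: int,
                        ) -> tuple[np.ndarray, GroundTruth]:
    """Render emitters as integrated-Gaussian PSFs with Poisson noise.

    ``positions_per_frame`` is a sequence of (n_i, 2) arrays of (x, y)
    emitter positions in pixel units; returns a float stack (frames, h, w)
    of Poisson-distributed counts and the per-frame truth.
    """
    if photon_count < 0 or background < 0:
        raise ValueError("photon_count and background must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    truth_frames = []
    for pos in positions_per_frame:
        pos = np.asarray(pos, float).reshape(-1, 2)
        if len(pos) and (np.any(pos < -1) or np.any(pos[:, 0] > shape[1])
                         or np.any(pos[:, 1] > shape[0])):
            raise ValueError("emitter positions outside image bounds")
        expected = _integrated_gaussian(shape, pos, psf_sigma, photon_count) + background
        if photon_count > 0 or background > 0:
            frame = rng.poisson(expected).astype(float)
        else:
            frame = expected
        frames.append(frame)
        truth_frames.append(pos)
    return np.stack(frames), GroundTruth(emitters=truth_frames)


# --------------------------------------------------------------------------
# widefield images with puncta
# --------------------------------------------------------------------------

def simulate_widefield_image(cluster_positions: np.ndarray,
                             cluster_amplitudes: np.ndarray,
                             shape: tuple[int, int], seed: int,
                             punctum_sigma: float = 2.0,
                             dendrite_mask: np.ndarray | None = None,
                             dendrite_level: float = 20.0,
                             background: float = 100.0,
                             noise_sigma: float = 4.0,
                             ) -> tuple[np.ndarray, GroundTruth]:
    """Widefield dendrite image: diffuse shaft signal + Gaussian puncta + noise.

    Cluster positions are (x, y) in px; amplitudes are peak photon counts
    above the diffuse level.  Noise is Poisson on the expected image plus
    Gaussian read noise of SD ``noise_sigma``.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("empty image dimensions")
    pos = np.asarray(cluster_positions, float).reshape(-1, 2)
    amp = np.asarray(cluster_amplitudes, float).reshape(-1)
    if len(pos) != len(amp):
        raise ValueError("positions and amplitudes must have equal length")
    if np.any(amp <= 0):
        raise ValueError("cluster amplitudes must be > 0")
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background))
    if dendrite_mask is not None:
        img += dendrite_level * dendrite_mask.astype(float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for (cx, cy), a in zip(pos, amp):
        img += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * punctum_sigma ** 2))
    noisy = rng.poisson(img).astype(float)
    if noise_sigma > 0:
        noisy += rng.normal(0.0, noise_sigma, size=shape)
    truth = pd.DataFrame({"x_px": pos[:, 0], "y_px": pos[:, 1], "amplitude": amp})
    return noisy, GroundTruth(clusters=truth)


# --------------------------------------------------------------------------
# FRAP curves
# --------------------------------------------------------------------------

def simulate_frap_curve(params: Mapping[str, float], times: np.ndarray,
                        noise_sd: float, seed: int,
                        ) -> tuple[FrapSeries, GroundTruth]:
    """FRAP series with two-time-constant recovery and optional baseline drift.

    ``params`` keys: bleach_depth (fraction of signal removed by the bleach),
    f (fast-component weight), tau1, tau2 (s), plateau (recovered fraction of
    the bleached signal), drift_slope (fractional baseline change per second,
    emulating cluster recruitment), and optionally acq_bleach_rate (fractional
    signal loss per second due to image acquisition), scale and background.

    Times are relative to the bleach: entries < 0 are pre-bleach.  The
    returned series carries a drift-free acquisition-bleaching reference and a
    drifting baseline curve, mirroring non-bleached clusters imaged alongside.
    """
    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    tau1 = float(params["tau1"]); tau2 = float(params["tau2"])
    f = float(params["f"])
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    if not 0.0 <= f <= 1.0:
        raise ValueError("fast fraction f must lie in [0, 1]")
    depth = float(params["bleach_depth"])
    plateau = float(params["plateau"])
    drift = float(params.get("drift_slope", 0.0))
    acq = float(params.get("acq_bleach_rate", 0.0))
    scale = float(params.get("scale", 1000.0))
    bg = float(params.get("background", 50.0))

    rng = np.random.default_rng(seed)
    pre = times < 0
    k = int(np.argmax(~pre))
    if k == 0:
        raise ValueError("need at least one pre-bleach time point (t < 0)")
    t0 = times - times[0]
    trend = 1.0 + drift * (times - times[0])        # recruitment trend
    acq_curve = np.exp(-acq * t0)                   # acquisition photobleaching

    # Post-bleach signal: the exchange process itself is drift-free (the
    # recruitment trend lives in the non-bleached baseline), so absolute-mode
    # recovery is independent of the drift by construction.
    rec = trend.copy()
    tp = times[k:]
    rec[k:] = trend[k] * ((1.0 - depth) + depth * plateau * (
        1.0 - f * np.exp(-tp / tau1) - (1.0 - f) * np.exp(-tp / tau2)))
    bleach = bg + scale * acq_curve * rec
    reference = bg + scale * acq_curve
    baseline = bg + scale * acq_curve * trend
    if noise_sd > 0:
        bleach = bleach + rng.normal(0.0, noise_sd * scale, size=times.shape)
    series = FrapSeries(times=times, bleach=bleach, reference=reference,
                        background=bg, bleach_index=k, baseline=baseline)
    truth = GroundTruth(frap={"bleach_depth": depth, "f": f, "tau1": tau1,
                              "tau2": tau2, "plateau": plateau,
                              "drift_slope": drift, "acq_bleach_rate": acq})
    return series, truth
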