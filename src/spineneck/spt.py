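"""Single-particle tracking: linking, MSD, diffusion estimation, classification.

The diffusion coefficient is obtained by fitting lags 2-5 of the MSD curve
with MSD(t) = 2*d*D*t + b (d = dimensionality of the displacement measure;
the conventional 2D fit uses 4Dt, the longitudinal 1D fit 2Dt).  On a
tubular membrane the 2D camera projection compresses transverse
displacements, biasing D low; projecting displacements onto the neck axis
(D_1Dlong) avoids that bias, which is why the 1D estimator is the default
for spine-neck trajectories.  Trajectories with D below 1e-4 um^2/s are
classified immobile, the scale at which a fitted slope is indistinguishable
from pure localization noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from shapely.geometry import Point, Polygon

__all__ = [
    "Trajectory", "MsdCurve", "DiffusionEstimate", "RegionLabel",
    "link_spots", "filter_trajectories", "compute_msd", "fit_diffusion",
    "classify_mobility", "classify_trajectory_region",
    "trajectories_to_table", "table_to_trajectories",
    "IMMOBILE_THRESHOLD",
]

#: um^2/s; trajectories with fitted D below this are considered immobile
IMMOBILE_THRESHOLD = 1e-4

MIN_TRAJECTORY_FRAMES = 15


@dataclass
class Trajectory:
    """Gap-free, time-ordered positions of one particle (nm)."""

    traj_id: int
    frames: np.ndarray            # strictly consecutive integers
    xy: np.ndarray                # (N, 2) nm
    dt: float                     # frame interval, s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        self.xy = np.asarray(self.xy, float)
        if len(self.frames) < 2:
            raise ValueError("trajectory needs >= 2 points")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be consecutive (no gaps)")
        if self.xy.shape != (len(self.frames), 2):
            raise ValueError("xy must be (N, 2)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MsdCurve:
    """MSD(n*dt) for lags n = 1..n_max, with the number of pairs per lag."""

    lags: np.ndarray              # 1..n_max
    msd: np.ndarray               # nm^2
    n_pairs: np.ndarray
    dimensionality: int           # 1 or 2


@dataclass
class DiffusionEstimate:
    D: float                      # um^2/s (negative values allowed, => immobile)
    intercept: float              # um^2
    fit_points: tuple[int, int]
    estimator: str                # D_2D | D_1Dlong
    mobile: bool
    traj_id: int | None = None


@dataclass
class RegionLabel:
    spine_class: str                       # "SP- spine" | "SP+ spine" | "dendrite"
    area_class: str | None = None          # "SP area" | "no SP area" (SP+ only)
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.area_class is not None and self.spine_class != "SP+ spine":
            raise ValueError("area_class is defined only for SP+ spines")


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def link_spots(locs: pd.DataFrame, max_disp: float, dt: float = 0.012,
               ) -> list[Trajectory]:
    """Frame-to-frame linking by globally optimal per-frame assignment.

    For each frame, active trajectory heads (last seen in the previous frame)
    are matched to current detections by minimising total squared
    displacement (Hungarian algorithm); links longer than ``max_disp`` nm are
    forbidden.  A trajectory that misses a frame is terminated — no gap
    closing — and unassigned detections start new trajectories.
    """
    if len(locs) == 0:
        return []
    locs = locs.sort_values("frame")
    frames = locs["frame"].to_numpy().astype(int)
    xy = locs[["x_nm", "y_nm"]].to_numpy()

    active: dict[int, tuple[int, np.ndarray]] = {}   # tid -> (last_frame, last_xy)
    paths: dict[int, list[tuple[int, np.ndarray]]] = {}
    next_id = 0
    for f in np.unique(frames):
        pts = xy[frames == f]
        heads = [(tid, p) for tid, (lf, p) in active.items() if lf == f - 1]
        assigned = set()
        if heads and len(pts):
            hp = np.stack([p for _, p in heads])
            cost = ((hp[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            big = max_disp ** 2 * 1e6 + 1.0
            cost = np.where(cost <= max_disp ** 2, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] >= big:
                    continue
                tid = heads[i][0]
                paths[tid].append((f, pts[j]))
                active[tid] = (f, pts[j])
                assigned.add(j)
        for j in range(len(pts)):
            if j not in assigned:
                paths[next_id] = [(f, pts[j])]
                active[next_id] = (f, pts[j])
                next_id += 1

    out = []
    for tid, steps in paths.items():
        if len(steps) < 2:
            continue
        fr = np.array([s[0] for s in steps])
        p = np.stack([s[1] for s in steps])
        out.append(Trajectory(traj_id=tid, frames=fr, xy=p, dt=dt))
    return out


def filter_trajectories(trajectories: list[Trajectory],
                        min_len: int = MIN_TRAJECTORY_FRAMES,
                        ) -> tuple[list[Trajectory], int]:
    """Keep trajectories with at least ``min_len`` consecutive frames."""
    kept = [t for t in trajectories if len(t) >= min_len]
    return kept, len(trajectories) - len(kept)


# --------------------------------------------------------------------------
# MSD and diffusion
# --------------------------------------------------------------------------

def compute_msd(traj: Trajectory, dimensionality: int = 2,
                axis: np.ndarray | None = None,
                max_lag: int | None = None) -> MsdCurve:
    """Time-averaged MSD over all overlapping pairs.

    2D: MSD(n*dt) = (N-n)^-1 * sum_i [(x_{i+n}-x_i)^2 + (y_{i+n}-y_i)^2].
    1D: same average over the squared projections ((r_{i+n}-r_i) . u)^2 for a
    unit axis direction ``axis`` (required; e.g. the neck axis), giving the
    longitudinal MSD free of 2D-projection bias on a curved membrane.
    """
    xy = traj.xy
    n_steps = len(xy)
    if dimensionality == 1:
        if axis is None:
            raise ValueError("1D MSD requires the axis direction u")
        axis = np.asarray(axis, float)
        if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
            raise ValueError("axis must be unit-norm")
    elif dimensionality != 2:
        raise ValueError("dimensionality must be 1 or 2")

    hi = n_steps - 1 if max_lag is None else min(max_lag, n_steps - 1)
    lags = np.arange(1, hi + 1)
    msd = np.empty(len(lags))
    for k, n in enumerate(lags):
        disp = xy[n:] - xy[:-n]
        if dimensionality == 2:
            msd[k] = np.mean((disp ** 2).sum(axis=1))
        else:
            msd[k] = np.mean((disp @ axis) ** 2)
    return MsdCurve(lags=lags, msd=msd, n_pairs=n_steps - lags,
                    dimensionality=dimensionality)


def principal_axis(xy: np.ndarray) -> np.ndarray:
    """First principal axis of a point set, sign fixed to positive x."""
    c = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    u = vt[0]
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    return u


def fit_diffusion(msd: MsdCurve, dt: float,
                  fit_points: tuple[int, int] = (2, 5),
                  traj_id: int | None = None) -> DiffusionEstimate:
    """OLS fit of MSD(t) = 2*d*D*t + b over lag indices ``fit_points``.

    Lags are 1-based indices into the MSD curve (default 2..5).  D is in
    um^2/s; negative fitted slopes are retained and classified immobile.
    """
    lo, hi = fit_points
    if hi - lo + 1 < 2:
        raise ValueError("need >= 2 fit points")
    if msd.lags[-1] < hi:
        raise ValueError(f"MSD curve has max lag {msd.lags[-1]}, need {hi} "
                         f"(trajectory too short)")
    sel = (msd.lags >= lo) & (msd.lags <= hi)
    t = msd.lags[sel] * dt                       # s
    y = msd.msd[sel] * 1e-6                      # nm^2 -> um^2
    slope, intercept = np.polyfit(t, y, 1)
    D = slope / (2.0 * msd.dimensionality)
    est = "D_1Dlong" if msd.dimensionality == 1 else "D_2D"
    return DiffusionEstimate(D=float(D), intercept=float(intercept),
                             fit_points=fit_points, estimator=est,
                             mobile=bool(D >= IMMOBILE_THRESHOLD),
                             traj_id=traj_id)


def classify_mobility(est: DiffusionEstimate,
                      threshold: float = IMMOBILE_THRESHOLD) -> bool:
    """Mobile iff D >= threshold (1e-4 um^2/s); negative D counts as immobile."""
    return bool(est.D >= threshold)


# --------------------------------------------------------------------------
# region classification
# --------------------------------------------------------------------------

def classify_trajectory_region(traj: Trajectory, sp_mask: np.ndarray,
                               mask_pixel_nm: float,
                               spine_rois: dict[str, list[tuple[float, float]]],
                               mask_origin_nm: tuple[float, float] = (0.0, 0.0),
                               on_mask_fraction: float = 0.5) -> RegionLabel:
    """Classify a trajectory by spine ROI and synaptopodin-mask coverage.

    The containing spine ROI is the polygon holding the majority of the
    trajectory's points (none -> "dendrite").  A spine is SP+ when its ROI
    contains any mask pixels; within SP+ spines the trajectory is labelled
    "SP area" when >= ``on_mask_fraction`` of its points fall on mask pixels.
    """
    pts = [Point(x, y) for x, y in traj.xy]
    best_name, best_frac = None, 0.0
    polys = {name: Polygon(coords) for name, coords in spine_rois.items()}
    for name, poly in polys.items():
        frac = np.mean([poly.contains(p) or poly.touches(p) for p in pts])
        if frac > best_frac:
            best_name, best_frac = name, frac
    if best_name is None or best_frac == 0.0:
        return RegionLabel(spine_class="dendrite")

    mask = np.asarray(sp_mask).astype(bool)
    h, w = mask.shape
    # does the spine ROI contain any SP mask pixel?
    ys, xs = np.nonzero(mask)
    mask_pts_x = xs * mask_pixel_nm + mask_origin_nm[0]
    mask_pts_y = ys * mask_pixel_nm + mask_origin_nm[1]
    poly = polys[best_name]
    minx, miny, maxx, maxy = poly.bounds
    near = ((mask_pts_x >= minx) & (mask_pts_x <= maxx)
            & (mask_pts_y >= miny) & (mask_pts_y <= maxy))
    sp_positive = any(poly.contains(Point(x, y))
                      for x, y in zip(mask_pts_x[near], mask_pts_y[near]))
    if not sp_positive:
        return RegionLabel(spine_class="SP- spine")

    cols = np.clip(np.round((traj.xy[:, 0] - mask_origin_nm[0]) / mask_pixel_nm
                            ).astype(int), 0, w - 1)
    rows = np.clip(np.round((traj.xy[:, 1] - mask_origin_nm[1]) / mask_pixel_nm
                            ).astype(int), 0, h - 1)
    on_mask = mask[rows, cols].mean()
    area = "SP area" if on_mask >= on_mask_fraction else "no SP area"
    return RegionLabel(spine_class="SP+ spine", area_class=area)


# --------------------------------------------------------------------------
# table conversions
# --------------------------------------------------------------------------

def trajectories_to_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    frames = [pd.DataFrame({"traj_id": t.traj_id, "frame": t.frames,
                            "x_nm": t.xy[:, 0], "y_nm": t.xy[:, 1]})
              for t in trajectories]
    if not frames:
        return pd.DataFrame(columns=["traj_id", "frame", "x_nm", "y_nm"])
    return pd.concat(frames, ignore_index=True)


def table_to_trajectories(table: pd.DataFrame, dt: float = 0.012
                          ) -> list[Trajectory]:
    out = []
    for tid, g in table.groupby("traj_id"):
        g = g.sort_values("frame")
        out.append(Trajectory(traj_id=int(tid), frames=g["frame"].to_numpy(),
                              xy=g[["x_nm", "y_nm"]].to_numpy(), dt=dt))
    return out
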