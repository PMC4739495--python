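"""FRAP (fluorescence recovery after photobleaching) normalization and kinetics.

A bleached region-of-interest time series is normalized against a non-bleached
reference (to remove acquisition photobleaching) and affinely rescaled so the
pre-bleach baseline maps to 1 and the first post-bleach point to 0.  The
normalized recovery is fitted with a two-time-constant exponential,

    F(t) = p * (1 - f * exp(-t/tau1) - (1 - f) * exp(-t/tau2)),

where ``p`` is the recovery plateau (mobile fraction), ``f`` the weight of the
fast component and ``tau1 <= tau2`` the two recovery time constants.

Two normalization modes are supported.  ``absolute`` removes background and
acquisition bleaching only.  ``baseline_relative`` additionally divides by the
time-matched trend of non-bleached clusters in the same condition, expressing
recovery relative to a possibly drifting pool (used when a treatment recruits
new molecules into clusters, so that absolute recovery can stay unchanged
while relative exchange slows down).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FrapSeries", "NormalizedFrap", "FrapFit", "normalize_frap", "fit_frap"]


@dataclass
class FrapSeries:
    """Raw FRAP record: bleach ROI, reference ROI and background over time.

    ``reference`` monitors acquisition photobleaching (non-bleached clusters
    in a drift-free condition); the optional ``baseline`` carries the
    condition-specific trend of non-bleached clusters (e.g. recruitment during
    a drug application) used by the ``baseline_relative`` mode.
    ``bleach_index`` is the index of the first post-bleach time point.
    """

    times: np.ndarray            # s
    bleach: np.ndarray           # a.u.
    reference: np.ndarray        # a.u.
    background: float | np.ndarray = 0.0
    bleach_index: int = 1
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleach = np.asarray(self.bleach, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (1 <= self.bleach_index < len(self.times)):
            raise ValueError("bleach_index must leave >=1 pre-bleach point")
        if self.bleach.shape != self.times.shape or self.reference.shape != self.times.shape:
            raise ValueError("bleach/reference must match times in length")


@dataclass
class NormalizedFrap:
    times: np.ndarray
    values: np.ndarray
    bleach_index: int
    mode: str

    @property
    def post_times(self) -> np.ndarray:
        """Times since bleach for the post-bleach points."""
        return self.times[self.bleach_index:] - self.times[self.bleach_index]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.bleach_index:]


@dataclass
class FrapFit:
    """Two-exponential recovery parameters with ordering tau1 <= tau2."""

    plateau: float
    fast_fraction: float
    tau1: float
    tau2: float
    residual_rms: float
    converged: bool = True
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    def recovery(self, t: np.ndarray) -> np.ndarray:
        return _two_exp(np.asarray(t, float), self.plateau, self.fast_fraction,
                        self.tau1, self.tau2)


def normalize_frap(series: FrapSeries,
                   mode: Literal["absolute", "baseline_relative"] = "absolute",
                   ) -> NormalizedFrap:
    """Background-correct, bleach-correct and rescale a FRAP series.

    Steps: subtract background; divide by the reference curve (normalized to
    its own pre-bleach mean) to undo acquisition photobleaching; in
    ``baseline_relative`` mode additionally divide by the baseline trend
    (normalized the same way); finally map the baseline level at time zero
    (the last pre-bleach point) to 1 and the first post-bleach point to 0.
    """
    if mode not in ("absolute", "baseline_relative"):
        raise ValueError(f"unknown mode {mode!r}")
    k = series.bleach_index
    b = series.bleach - series.background
    ref = series.reference - series.background
    ref_pre = ref[:k].mean()
    if ref_pre == 0 or np.any(ref == 0):
        raise ValueError("reference curve hits zero after background subtraction")
    y = b / (ref / ref_pre)
    if mode == "baseline_relative":
        base = series.baseline if series.baseline is not None else series.reference
        base = np.asarray(base, float) - series.background
        if np.any(base == 0):
            raise ValueError("baseline curve hits zero after background subtraction")
        y = y / (base / base[:k].mean())
    pre = y[k - 1]          # baseline level at time zero (last pre-bleach point)
    post0 = y[k]
    if pre == post0:
        raise ValueError("pre-bleach level equals first post-bleach point; cannot rescale")
    y = (y - post0) / (pre - post0)
    return NormalizedFrap(times=series.times.copy(), values=y, bleach_index=k, mode=mode)


def _two_exp(t, p, f, tau1, tau2):
    return p * (1.0 - f * np.exp(-t / tau1) - (1.0 - f) * np.exp(-t / tau2))


def _single_exp(t, p, tau):
    return p * (1.0 - np.exp(-t / tau))


def fit_frap(norm: NormalizedFrap,
             n_starts: int = 5,
             degeneracy_tau_ratio: float = 1.5,
             degeneracy_fraction: float = 0.05) -> FrapFit:
    """Fit the two-time-constant recovery model to a normalized curve.

    Nonlinear least squares with a deterministic multi-start grid of time
    constants spanning the sampled decades; parameters are bounded
    (p in [0, 1.5], f in [0, 1], tau in [dt, 10 * t_max]) and reported with
    the ordering convention tau1 <= tau2.  Fits that collapse onto a single
    exponential (f near 0/1 or tau1 ~ tau2) are flagged ``degenerate``.
    """
    t = norm.post_times
    y = norm.post_values
    if len(t) < 8:
        raise ValueError(f"need >=8 post-bleach points, got {len(t)}")
    dt = max(np.min(np.diff(t)), 1e-9)
    t_max = t[-1]
    tau_lo, tau_hi = dt, 10.0 * t_max
    bounds = ([0.0, 0.0, tau_lo, tau_lo], [1.5, 1.0, tau_hi, tau_hi])
    p0_p = float(np.clip(np.median(y[-max(3, len(y) // 10):]), 0.05, 1.4))
    tau_grid = np.geomspace(max(tau_lo, t_max / 100.0), t_max, n_starts)

    best = None
    for i, tau1 in enumerate(tau_grid):
        for tau2 in tau_grid[i:]:
            for f0 in (0.3, 0.7):
                try:
                    popt, _ = curve_fit(_two_exp, t, y,
                                        p0=[p0_p, f0, tau1, tau2],
                                        bounds=bounds, maxfev=5000)
                except RuntimeError:
                    continue
                sse = float(np.sum((y - _two_exp(t, *popt)) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, popt)
    flags: list[str] = []
    if best is None:
        return FrapFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                       converged=False, flags=["no_convergence"])
    sse, (p, f, tau1, tau2) = best
    if tau1 > tau2:  # ordering convention; f is the weight of the fast term
        tau1, tau2, f = tau2, tau1, 1.0 - f
    degenerate = (f < degeneracy_fraction or f > 1.0 - degeneracy_fraction
                  or tau2 / tau1 < degeneracy_tau_ratio)
    if degenerate:
        flags.append("single_exponential_like")
    rms = float(np.sqrt(sse / len(t)))
    return FrapFit(plateau=float(p), fast_fraction=float(f),
                   tau1=float(tau1), tau2=float(tau2), residual_rms=rms,
                   converged=True, degenerate=degenerate, flags=flags)


def fit_single_exponential(norm: NormalizedFrap) -> tuple[float, float, float]:
    """Single-exponential reference fit; returns (plateau, tau, residual_rms).

    Used as the nested-model baseline: the two-exponential fit can never have
    a larger residual than this on the same data.
    """
    t, y = norm.post_times, norm.post_values
    t_max = t[-1]
    best = None
    for tau0 in np.geomspace(max(t_max / 100.0, 1e-9), t_max, 5):
        try:
            popt, _ = curve_fit(_single_exp, t, y, p0=[max(y[-1], 0.1), tau0],
                                bounds=([0.0, 1e-9], [1.5, 10 * t_max]), maxfev=5000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - _single_exp(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return np.nan, np.nan, np.nan
    sse, (p, tau) = best
    return float(p), float(tau), float(np.sqrt(sse / len(t)))
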