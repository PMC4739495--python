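"""End-to-end demo pipeline: simulate, analyse, and report with a manifest.

Conditions (control / 4AP / latA) are generator parameter presets only: latA
widens the synaptopodin domain (66 -> 84 nm) and lifts the diffusivity inside
the SP area to the no-SP level; 4AP scales diffusivities up everywhere while
leaving the domain widths unchanged.  No pharmacology is modelled beyond
these parameter changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as snio
from .frap import fit_frap, normalize_frap
from .profile import NeckAxisROI, detection_histogram_fwhm, domain_gap
from .reporting import compare_groups
from .segmentation import WaveletParams, atrous_decompose, cluster_density, threshold_mask
from .spt import compute_msd, fit_diffusion, table_to_trajectories
from .synthetic import (NO_SP_AREA, SP_AREA, GroundTruth, NeckGeometry,
                        SimulationConfig, simulate_detection_cloud,
                        simulate_frap_curve, simulate_trajectories_on_cylinder,
                        simulate_widefield_image)

__all__ = ["RunConfig", "CONDITIONS", "run_pipeline"]

#: per-condition generator presets (domain widths nm, diffusivities um^2/s)
CONDITIONS: dict[str, dict] = {
    "control": {"sp_diameter": 66.0, "actin_diameter": 105.0,
                "outer_diameter": 195.0,
                "D_map": {SP_AREA: 0.025, NO_SP_AREA: 0.05}},
    "4AP":     {"sp_diameter": 66.0, "actin_diameter": 105.0,
                "outer_diameter": 195.0,
                "D_map": {SP_AREA: 0.05, NO_SP_AREA: 0.1}},
    "latA":    {"sp_diameter": 84.0, "actin_diameter": 100.0,
                "outer_diameter": 195.0,
                "D_map": {SP_AREA: 0.05, NO_SP_AREA: 0.05}},
}

_KNOWN_KEYS = {"condition", "seed", "n_trajectories", "n_frames",
               "frame_interval", "loc_noise_sigma", "pixel_size",
               "n_detections", "cloud_sigma_xy", "outdir"}


@dataclass
class RunConfig:
    condition: str = "control"
    seed: int = 0
    n_trajectories: int = 100
    n_frames: int = 100
    frame_interval: float = 0.012
    loc_noise_sigma: float = 15.0
    pixel_size: float = 107.0
    n_detections: int = 10000
    cloud_sigma_xy: float = 13.0
    outdir: str = "spineneck_run"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; "
                             f"expected one of {sorted(CONDITIONS)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _stage(name):
    """Decorator: prefix any stage failure with the stage name."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return inner
    return wrap


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Simulate -> track -> profile -> segment -> FRAP -> report.

    Writes CSV tables, a JSON report and a manifest (seed, config hash,
    outputs) to the output directory and returns its path.  Reruns with the
    same config and seed produce identical manifests.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = CONDITIONS[config.condition]
    geom = NeckGeometry(outer_diameter=preset["outer_diameter"],
                        actin_diameter=preset["actin_diameter"],
                        sp_diameter=preset["sp_diameter"])
    report: dict = {"condition": config.condition, "seed": config.seed}
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    sub_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    # --- super-resolution clouds and domain widths ---
    @_stage("profile")
    def profile_stage():
        roi = NeckAxisROI(geom.axis_start, geom.axis_end, band_width=100.0)
        widths = {}
        for i, species in enumerate(("SP", "actin", "membrane")):
            locs, _ = simulate_detection_cloud(geom, species, config.n_detections,
                                               config.cloud_sigma_xy,
                                               seed=sub_seed[0] + i)
            snio.write_locs_csv(locs, outdir / f"cloud_{species}.csv")
            widths[species] = detection_histogram_fwhm(locs, roi).fwhm_nm
        widths["gap_membrane_sp_nm"] = domain_gap(widths["membrane"], widths["SP"])
        widths["ordering_sp_lt_actin_lt_membrane"] = bool(
            widths["SP"] < widths["actin"] < widths["membrane"])
        return widths
    report["fwhm_nm"] = profile_stage()

    # --- trajectories and diffusion ---
    @_stage("track")
    def track_stage():
        cfg = SimulationConfig(frame_interval=config.frame_interval,
                               n_frames=config.n_frames, D_map=dict(preset["D_map"]),
                               loc_noise_sigma=config.loc_noise_sigma,
                               pixel_size=config.pixel_size, rng_seed=sub_seed[1])
        table, truth = simulate_trajectories_on_cylinder(geom, cfg,
                                                         config.n_trajectories)
        snio.write_traj_csv(table, outdir / "trajectories.csv")
        u = geom.axis_unit
        by_region: dict[str, list[float]] = {SP_AREA: [], NO_SP_AREA: []}
        for traj in table_to_trajectories(table, dt=cfg.frame_interval):
            est = fit_diffusion(compute_msd(traj, 1, axis=u), cfg.frame_interval,
                                traj_id=traj.traj_id)
            if est.mobile:
                region = truth.trajectories.loc[truth.trajectories["traj_id"]
                                                == traj.traj_id, "region"].iloc[0]
                by_region[region].append(est.D)
        out = {r: {"n": len(v), "median_D": float(np.median(v)) if v else None}
               for r, v in by_region.items()}
        if all(len(v) >= 3 for v in by_region.values()):
            cmp = compare_groups({k: np.array(v) for k, v in by_region.items()},
                                 test="KS")
            out["ks_pvalue"] = cmp.pvalue
        return out
    report["diffusion"] = track_stage()

    # --- widefield segmentation ---
    @_stage("segment")
    def segment_stage():
        rng = np.random.default_rng(sub_seed[2])
        n_puncta = 20
        pos = np.stack([rng.uniform(10, 190, n_puncta),
                        rng.uniform(20, 44, n_puncta)], axis=1)
        img, truth = simulate_widefield_image(pos, np.full(n_puncta, 120.0),
                                              shape=(64, 200), seed=sub_seed[2])
        planes, _ = atrous_decompose(img, 3)
        masks = threshold_mask(planes, WaveletParams(k_sigma=2.0))
        length_um = 200 * config.pixel_size / 1000.0
        return {"n_components": masks.n_components,
                "density_per_um": cluster_density(masks, length_um),
                "n_true_puncta": len(truth.clusters)}
    report["segmentation"] = segment_stage()

    # --- FRAP ---
    @_stage("frap")
    def frap_stage():
        times = np.concatenate([np.arange(-20.0, 0, 5.0), np.arange(0.0, 601.0, 5.0)])
        drift = 0.002 if config.condition == "latA" else 0.0
        series, truth = simulate_frap_curve(
            {"bleach_depth": 0.8, "f": 0.6, "tau1": 20.0, "tau2": 300.0,
             "plateau": 0.8, "drift_slope": drift}, times, noise_sd=0.01,
            seed=sub_seed[3])
        fit = fit_frap(normalize_frap(series, "absolute"))
        return {"plateau": fit.plateau, "fast_fraction": fit.fast_fraction,
                "tau1_s": fit.tau1, "tau2_s": fit.tau2,
                "true": truth.frap}
    report["frap"] = frap_stage()

    snio.write_json(report, outdir / "report.json")
    manifest = {"config": asdict(config), "config_hash": config.content_hash(),
                "seed": config.seed,
                "outputs": sorted(p.name for p in outdir.iterdir()
                                  if p.name != "manifest.json")}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]
    snio.write_json(manifest, outdir / "manifest.json")
    return outdir
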