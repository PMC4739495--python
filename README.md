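# spineneck

Quantitative analysis of nanoscale organisation and membrane-protein
diffusion in **dendritic spine necks**.

The thin neck connecting a dendritic spine's head to its dendrite acts as a
diffusion barrier for synaptic membrane proteins. Synaptopodin (SP), an
actin-associated protein enriched in spine necks, occupies only the inner
part of the neck and correlates with slower diffusion of large receptors
such as mGluR5. Testing such claims requires four quantitative pipelines,
all implemented here:

* **Single-particle tracking (SPT)** — linking quantum-dot detections into
  trajectories, computing time-averaged mean squared displacement
  `MSD(n·dt) = (N−n)⁻¹ Σᵢ [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²]`, and fitting
  lags 2–5 with `MSD(t) = 2Dt + b`. Because a neck is a ~100–200 nm
  tube, 2D camera projections compress transverse displacements and bias D
  low; projecting displacements onto the neck axis gives the unbiased
  longitudinal estimator **D₁D,long**. Trajectories with
  D < 10⁻⁴ µm²/s are classified immobile; only trajectories with ≥ 15
  consecutive frames are analysed.
* **STORM/PALM localization** — spot detection, sub-pixel 2D Gaussian PSF
  fitting, fiducial-based drift correction, pointing accuracy (per-axis SD
  of repeated detections of one fluorophore), and pointillist rendering
  with unit-integral σ = 10 nm Gaussians.
* **Domain-width (FWHM) profiling** — intensity profiles across the neck in
  rendered images, and transverse detection histograms inside a 200 nm
  segment; the radial gap between nested domains is
  `(FWHM_outer − FWHM_inner) / 2`.
* **À-trous wavelet segmentation** — B3-spline undecimated wavelet planes,
  robust (MAD) thresholding into binary cluster masks, integrated-intensity
  quantification, cluster densities (on dendrites > 10 µm) and exclusive
  neck/head/base compartment assignment.
* **FRAP kinetics** — normalization of bleach-ROI series against
  non-bleached references and two-time-constant recovery fits
  `F(t) = p(1 − f·e^(−t/τ₁) − (1−f)·e^(−t/τ₂))`.

Every pipeline stage is driven by a **synthetic-data generator** that
emulates the imaging conditions (Brownian motion on a cylindrical membrane
at 12 ms frame interval, detection clouds for the nested 66/105/195 nm
SP/F-actin/membrane domains with 12–14 nm pointing accuracy, raw PSF
movies, widefield puncta images, FRAP curves) with full ground truth, so
every estimator is verifiable end to end without any external data.

## Worked example

```python
import numpy as np
from spineneck import (NeckGeometry, NeckAxisROI, SimulationConfig,
                       simulate_detection_cloud, detection_histogram_fwhm,
                       domain_gap, simulate_trajectories_on_cylinder,
                       compute_msd, fit_diffusion)
from spineneck.spt import table_to_trajectories

geom = NeckGeometry()                  # SP 66 / F-actin 105 / membrane 195 nm
roi = NeckAxisROI(geom.axis_start, geom.axis_end)

widths = {}
for i, species in enumerate(("SP", "actin", "membrane")):
    locs, _ = simulate_detection_cloud(geom, species, 20_000, sigma_xy=13.0, seed=i)
    widths[species] = detection_histogram_fwhm(locs, roi).fwhm_nm
print(f"projected widths (nm): SP {widths['SP']:.1f}  "
      f"F-actin {widths['actin']:.1f}  membrane {widths['membrane']:.1f}")
print(f"SP-to-actin-edge gap: {domain_gap(widths['actin'], widths['SP']):.1f} nm")

cfg = SimulationConfig(n_frames=100, rng_seed=0)   # D: 0.025 in SP, 0.05 outside
table, truth = simulate_trajectories_on_cylinder(geom, cfg, 200)
med = {}
for region in ("SP area", "no SP area"):
    ids = set(truth.trajectories.query("region == @region")["traj_id"])
    ds = [fit_diffusion(compute_msd(t, 1, axis=geom.axis_unit), cfg.frame_interval).D
          for t in table_to_trajectories(table, cfg.frame_interval)
          if t.traj_id in ids]
    med[region] = np.median(ds)
print(f"median D_1Dlong (um^2/s): SP area {med['SP area']:.4f}  "
      f"no-SP area {med['no SP area']:.4f}")
```

Output:

```
projected widths (nm): SP 58.5  F-actin 85.2  membrane 208.8
SP-to-actin-edge gap: 13.3 nm
median D_1Dlong (um^2/s): SP area 0.0278  no-SP area 0.0464
```

The measured widths preserve the SP < F-actin < membrane ordering. They are
not equal to the 3D domain diameters: a filled cylinder of diameter d
projects to a chord-length density whose FWHM is d·√3/2, broadened by the
localization blur — the SP rod (66 nm) measures ≈ 58 nm, the filled
F-actin core (105 nm) ≈ 85 nm, while the hollow membrane shell (195 nm)
measures wider than its diameter because its projection peaks at the tube
edges. The diffusion medians recover the simulated region-dependent
diffusivities (0.025 inside the SP area vs 0.05 µm²/s outside).

A thin CLI wraps the same functions:

```sh
spineneck simulate cloud --species actin --n 10000 --seed 1 --out locs.csv
spineneck profile --locs locs.csv --roi roi.json
spineneck run --condition latA --seed 3 --out results_latA
```

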