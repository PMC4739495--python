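# Methods

This note documents the models, parameter choices and numerical decisions
behind `spineneck`, in the spirit of the methods documentation shipped by
simulation and statistics packages: what each component assumes, which knobs
matter, and what the synthetic-data tests do and do not demonstrate about
real data.

## Spine-neck geometry model

A neck is modelled as three coaxial domains along a 2D axis segment
(`NeckGeometry`): a filled synaptopodin (SP) rod (default diameter 66 nm)
restricted to a sub-interval of the axis, a filled F-actin cylinder
(105 nm) spanning the whole axis, and an infinitely thin membrane shell
(195 nm). Diameters are constrained to `sp ≤ actin ≤ outer`. SP and
F-actin are sampled as *volumes* because their labels (dendra-SP,
phalloidin) are volumetric probes of cytoplasmic structures; the membrane
probe is membrane-bound, hence a surface shell. The default diameters are
the measured widths of the three domains in spine necks; treating measured
FWHMs as 3D diameters is an approximation (see "Projection arithmetic").

## Synthetic-data generators

All generators take an explicit integer seed (`numpy.random.default_rng`),
use no global state, and are bit-reproducible.

**Trajectories on a cylinder.** Brownian motion lives on the unwrapped
membrane surface with coordinates (z, s = rθ); per-frame steps on each
surface axis are N(0, 2·D·Δt) with D chosen by the region containing the
current z. Defaults: Δt = 12 ms (streamed quantum-dot recording),
localization noise 15 nm per axis (middle of the 10–20 nm accuracy range),
D = 0.05 µm²/s outside and 0.025 µm²/s inside the SP segment (a 2× slowdown
of the kind the SPT pipeline must detect). Region boundaries are sharp —
no transition profile is modelled. Curvature enters only through the
projection (x = z along the axis, y = r·sinθ); metric corrections beyond
unwrapping are ignored, which is consistent with the locally flat
assumption of the MSD estimator being tested. Longitudinal motion is
unbounded: real trajectories continue into the spine head and dendrite, so
the neck ends are not walls. (Reflecting ends on a 1 µm segment would
artificially confine the motion and bias the fitted D roughly 10% low at
lags 2–5 — an artifact of the boundary model, not of the estimator.)

**Detection clouds.** Uniform 3D sampling in the species' domain,
orthogonal projection to the camera plane, isotropic Gaussian localization
error per axis (default 13 nm, between the measured 12.2 nm (dendra) and
14.4 nm (A647) pointing accuracies). A filled cylinder of radius R projects
to the chord-length density ∝ √(R²−x²) with FWHM R√3; the shell projects to
∝ 1/√(R²−x²), peaking at the tube edges. These closed forms are the test
oracles (after numeric convolution with the noise kernel).

**Spot movies.** Emitters are rendered as pixel-integrated Gaussians
(difference of error functions), plus constant background, with Poisson
noise on the expected counts. Fluorophore photophysics (blinking), 3D
defocus and chromatic effects are not modelled.

**Widefield images.** Constant background (+ optional diffuse dendrite
level), Gaussian puncta of σ = 2 px, Poisson noise plus Gaussian read
noise. Puncta amplitude 100 counts over a background of 100 with 4-count
read noise gives SNR well above the detection regime being tested.

**FRAP curves.** Pre-bleach baseline (optionally drifting at
`drift_slope` s⁻¹, emulating cluster recruitment during latrunculin A),
instantaneous bleach of depth `bleach_depth`, recovery
p·(1 − f·e^(−t/τ₁) − (1−f)·e^(−t/τ₂)). The series carries two companion
curves: a drift-free acquisition-photobleaching reference, and a baseline
trend that continues to drift after the bleach. The exchange process itself
is simulated drift-free, so absolute-mode recovery is independent of
recruitment by construction while baseline-relative recovery slows — the
directional behaviour the normalization modes are designed to separate.

## SPT pipeline

* **MSD.** Time-averaged over all N−n overlapping pairs. The curve carries
  units of length²; the diffusion fit `MSD(t) = 2·d·D·t + b` (d = 1 or 2)
  is an ordinary least-squares line through lag indices 2–5 (1-based).
  The intercept b absorbs the static localization-error term 2σ²; negative
  fitted D is retained and classified immobile.
* **Longitudinal estimator.** Displacements are projected onto a unit axis
  û (from the ROI, or the trajectory's first principal axis with the sign
  fixed to positive x). On a tube, the 2D estimate is biased low because
  transverse projected motion saturates near ±R; the longitudinal estimate
  is not. Simulations at R = 52.5 nm, D = 0.05 µm²/s reproduce both facts.
* **Immobility.** Mobile ⇔ D ≥ 10⁻⁴ µm²/s. Design analysis: on pure
  localization noise the lag-2–5 slope has SD ≈ 2σ²-scale fluctuations —
  about 5×10⁻⁵ µm²/s for 5000-frame recordings at σ = 10 nm, but several
  10⁻⁴ for short, noisier trajectories. The immobile-population test
  therefore uses full-length recordings (stationary particles are
  trackable for the entire movie) at the 10 nm accuracy characteristic of
  bright, motion-blur-free emitters; under those conditions ≥ 95% of
  immobile particles fall below the threshold. Short immobile fragments
  cannot be classified reliably at this threshold — a property of the
  estimator, not of the implementation.
* **Linking.** Per-frame globally optimal assignment (Hungarian algorithm
  on squared distances) with a hard `max_disp` gate; misses terminate a
  trajectory (no gap closing); unmatched detections seed new trajectories.
  Only trajectories with ≥ 15 consecutive frames are analysed.
* **Region classification.** A spine is SP+ when its ROI polygon contains
  any mask pixel; a trajectory is "SP area" when ≥ 50% of its points fall
  on mask pixels (the 50% cut is a design choice; agreement with simulator
  truth is ≥ 90% under default conditions, limited by trajectories that
  straddle the segment boundary).

## Localization pipeline

* **Fitting.** Unweighted least squares of an isotropic 2D Gaussian
  (amplitude, sub-pixel center, σ, offset) in a 7×7 px window. Fits are
  marked invalid — never raised — when the window is flat, the optimiser
  fails, or σ leaves [0.5, 4]× the nominal PSF σ (rejecting overlapping
  emitters). In the shot-noise limit the unweighted LSQ center estimator
  carries about twice the information-bound variance,
  σ_loc² ≈ 2(s² + a²/12)/N; Monte-Carlo SDs match this within a few
  percent, and precision scales as photons^(−1/2) over a decade.
* **Drift.** Per-frame mean fiducial displacement from the reference
  frame, interpolated across gaps, smoothed with a local-linear
  (Savitzky–Golay, polyorder 1) filter over 101 frames. A plain moving
  average was rejected because its asymmetric edge windows bias the trace
  at the start and end of the movie for any monotone drift; the
  local-linear filter is the edge-correct form of the same smoother.
  Dual-colour alignment is a rigid translation from matched fiducial
  centroids.
* **Rendering.** Each detection contributes a Gaussian of σ = 10 nm
  integrated exactly over output pixels (default 5 nm), so rendering is
  linear and each detection integrates to 1.

## FWHM profiling

Profiles are sampled perpendicular to a user-supplied neck axis (bilinear
interpolation), averaged over a band along the axis. Background is the
median of the outer 20% of profile positions (the tails); half-max
crossings are located by linear interpolation scanning inward from the
profile ends, so two-edge-peaked membrane profiles yield their envelope
width and are flagged `multi_peak` (an optional 10 nm Gaussian
pre-smoothing regularises them). Detection histograms use 10 nm bins inside
a 200 nm axial segment and require ≥ 50 detections. Profiles are centered
on the fitted peak — a deterministic surrogate for manual alignment.
The FWHM estimate is invariant to affine intensity transforms and monotone
in the true rod diameter over 40–150 nm at σ_loc = 12 nm.

**Projection arithmetic.** The measured projected FWHM of a filled rod is
≈ √3/2 of its diameter (before blur), so clouds generated from
diameter = printed-width defaults measure somewhat narrower than those
printed widths, and the hollow shell measures wider. The pipeline's
verifiable claims are therefore the ordering SP < F-actin < membrane, the
agreement of both measurement routes (rendered profile vs detection
histogram, within 10% on 10⁴-detection clouds), and agreement with the
analytic convolution oracle — not numeric equality of simulated widths
with the real measurements. The domain gap is (outer − inner)/2; with the
printed control widths (105, 66) it is 19.5 ≈ 20 nm, and with the
latrunculin-A widths (100, 84) it is 8 nm.

## Wavelet segmentation

B3-spline à-trous transform (kernel [1,4,6,4,1]/16, holes doubling per
scale, mirror boundaries); plane i = smooth_{i−1} − smooth_i, so the
decomposition reconstructs exactly to machine precision. Masks threshold
plane 2 at k·(1.4826·MAD) — MAD rather than SD so bright puncta do not
inflate their own threshold — followed by an area opening (min 4 px).
Defaults (3 scales, detection on plane 2, k = 1 for quantification masks,
k ≈ 2–3 for detection) are the conventional choices for this transform;
the mask is monotone (shrinking) in k. Integrated intensities subtract
area × median-outside-mask background per channel. Cluster densities are
only reported for dendrite segments longer than 10 µm; compartment
assignment is exclusive with priority neck > head > base on boundary ties.

## FRAP

Normalization: background subtraction; division by the acquisition-
bleaching reference (normalized to its pre-bleach mean); affine anchoring
of the baseline level at time zero (the last pre-bleach point) to 1 and the
first post-bleach point to 0. The anchor is a single point, not the
pre-bleach mean, so a drifting baseline does not distort the recovery
amplitude. `baseline_relative` mode additionally divides by the
time-matched non-bleached baseline trend; it is the mode in which
recruitment-driven baseline growth reads out as slowed relative exchange.
Because one non-bleached-cluster curve cannot separate acquisition
bleaching from condition-specific recruitment, `FrapSeries` carries them as
two fields (`reference`, optional `baseline`); the simulator emits both.

Fitting: bounded nonlinear least squares (p ∈ [0, 1.5], f ∈ [0, 1],
τ ∈ [dt, 10·t_max]) with a deterministic multi-start grid of (τ₁, τ₂) pairs
over the sampled decades and two starts for f; the ordering τ₁ ≤ τ₂ is
enforced by swapping (with f ↦ 1−f). Fits with f near 0/1 or τ₂/τ₁ < 1.5
are flagged single-exponential-like; by model nesting the two-exponential
residual never exceeds the single-exponential one.

## Group comparison

Mann-Whitney U and two-sample Kolmogorov-Smirnov come from scipy;
Kruskal-Wallis is followed by Dunn's rank-based pairwise z tests with tie
correction and Bonferroni adjustment (implemented here; no installed
package provides Dunn's test). Reports carry median and quartiles per
group with group sizes.

## Conditions and the demo pipeline

Control / 4AP / latrunculin-A are generator presets only: latA widens the
SP rod 66 → 84 nm, keeps the actin core at ~100 nm, and raises D inside
the SP area to the outside level; 4AP scales diffusivities up uniformly.
`run_pipeline` chains simulate → profile → track → segment → FRAP and
writes a manifest (config hash, seed, outputs) that is bit-identical across
reruns with the same seed.

## Problem sizes

The test suite and the acceptance script use: 10 batches × 300 trajectories
× 100 frames for diffusion recovery; 100 × 5000-frame trajectories for the
immobility rule; 5×10⁴-detection clouds (≈10⁴ inside the 200 nm segment)
for the FWHM oracle and 20 seeds × 5000 detections for the ordering check;
20 widefield images for segmentation recall and 5 × 256² noise images for
the false-positive rate; 50 noisy FRAP curves; 150 frames × 3 photon levels
for precision scaling. These sizes put the Monte-Carlo error comfortably
below each assertion's tolerance while keeping a full run in tens of
seconds.

## Known limitations

* No 3D optics (astigmatism/defocus), no blinking kinetics, no chromatic
  aberration, no sCMOS noise maps, no multi-emitter fitting.
* No gap closing or confinement/HMM trajectory models; the linker assumes
  sparse detections.
* The neck axis is user-supplied (or simulation truth); automatic axis
  finding and dendrite tracing are out of scope.
* Passing synthetic tests demonstrates estimator correctness under the
  generator's assumptions (ideal Gaussian noise, sharp region boundaries,
  uniform labelling); real data add heterogeneous labelling density,
  background structure and photophysics that these tests do not probe.
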