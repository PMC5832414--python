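# Methods

This note records the models, numerical choices, and open design decisions
behind `holostim`, and what the synthetic-data tests do and do not
demonstrate.

## Optical model

**Coordinates.** The SLM plane is conjugate to the objective pupil. Pupil
coordinates (u, v) are physical spatial frequencies in cycles/µm; the SLM's
N×N grid spans the pupil diameter, so the sample spacing is
du = 2·u_max/N with u_max = NA/λ. With this convention the tilt term
2π(x·u + y·v) is an exact Fourier shift in microns, and the Nyquist limit of
the grid gives the addressable lateral range |x| ≤ N/(4·u_max) (≈ 380 µm at
NA 0.35, λ 1.04 µm, N = 512) — violations are an error, never silent
wrapping. Zernike polynomials are evaluated on the unit disk
ρ = √(u²+v²)/u_max.

**Defocus with spherical-aberration compensation.** Refocusing by z µm in a
medium of index n requires the pupil phase (n·z/λ)·√(1 − sin²α·ρ²),
sinα = NA/n. We expand this in the √3/√5/√7-normalized Zernike radial basis
and keep defocus (Z₂⁰) plus first and second spherical aberration
(Z₄⁰, Z₆⁰):

    C₂⁰(z) = n·k·z·sin²α/(8π√3) · (1 + ¼ sin²α + 9/80 sin⁴α + 1/16 sin⁶α)
    C₄⁰(z) = n·k·z·sin⁴α/(96π√5) · (1 + ¾ sin²α + 15/28 sin⁴α)
    C₆⁰(z) = n·k·z·sin⁶α/(640π√7) · (1 + 5/4 sin²α)

Each coefficient is linear in z. The truncation error at NA 0.35 is below
10⁻⁵ waves at z = 50 µm (a unit test checks the series against the exact
closed form). An `effective_na` knob feeds the C coefficients only; it
mirrors the bench practice of tuning the commanded-vs-realized defocus.
In the clean simulation the physical NA already places foci within
tolerance, so the knob defaults to the physical NA.

**Sign convention.** With the propagation kernel exp(+j·k_z·z), a positive
Zernike block focuses at +z. The convention is arbitrated numerically: the
propagation oracle confirms that commanded and realized depth agree over
[−200, +90] µm and beyond.

**Superposition vs Gerchberg–Saxton.** The superposition hologram is the
phase of the weighted sum of single-focus fields. Discarding the amplitude
of that sum costs per-focus power fidelity of order 10% (measured ~5% for 12
well-separated weighted targets) — acceptable for soma targeting, and the
efficiency-compensation path corrects systematic (position-dependent) loss.
One caveat discovered in testing: perfectly periodic equal-weight target
lattices make the summed field degenerate and concentrate energy in a few
diffraction orders; realistic (cell-like, jittered) arrangements do not
exhibit this. The GS route optimizes arbitrary per-plane amplitude targets:
propagate with the aberration-compensated kernel, impose the target
amplitude, back-propagate, sum over planes, re-impose the pupil amplitude
(uniform disk by default, Gaussian by config). Initial phase is uniform
random from the caller's seed; iteration caps at 50 with early stop when the
two-photon target correlation changes by < 1e-4. The per-iteration
correlation trace is kept in `mask.meta`.

**Zeroth order.** An unmodulated-field fraction can be added before
propagation, and the physical pellicle block is modeled by zeroing a disk
(default 5 µm radius at the sample) in the intermediate (z = 0) focal
plane. Both default off.

## Propagation oracle

Debye-type single-FFT-per-plane propagation with the exact nonparaxial
k_z = 2π√((n/λ)² − u² − v²); evanescent components are dropped (none exist
inside the pupil since NA < n). The pupil grid is zero-padded by an
oversampling factor ≥ 2 so the intensity (bandwidth 2·u_max) is
Nyquist-sampled; the default factor 2 gives 0.74 µm lateral pixels at
NA 0.35. Unitary FFTs make per-plane energy exactly conserved (checked to
1e-6); the full grid is always propagated and only then cropped, so energy
bookkeeping is unaffected by the requested field of view.

Foci are local maxima of the squared intensity above a relative threshold,
non-maximum-suppressed by physical distance (strongest first; ties broken
toward lower z, then y, then x) and refined per axis by a 3-point quadratic
fit, which also refines the peak value. Because the lateral PSF (~1.5 µm
FWHM) is only ~2 pixels wide, single-voxel peaks under-measure beamlet
strength; `focus_power` therefore integrates intensity over a lateral disk
(default 3 µm radius) in the focus plane and is the quantity used for
weight-proportionality and uniformity checks. Axial FWHM is measured on the
on-axis squared-intensity profile with linear interpolation at half maximum
and requires ≤ 1 µm plane spacing. Foci are matched to requests by optimal
(Hungarian) assignment with a 10 µm gating distance.

The clean NA 0.35 / 1040 nm / water simulation gives an axial two-photon
FWHM of 14.16 µm. A measured value on a real instrument includes residual
system aberrations and is expected a few percent wider; comparisons use a
±15% band.

## Calibration

Per-depth 2D affines are fitted by linear least squares on ≥ 3 non-collinear
correspondences (the standard fixture is a 7×7 grid over 240×240 µm);
the stored residual is the per-coordinate RMS, directly comparable to the
localization noise σ. Between calibration depths (every 25 µm) the matrix
and offset are interpolated elementwise — exact at the knots, piecewise
linear in between. Outside the calibrated band the nearest transform is
returned with a warning up to one depth step; farther out is an error.
Shear is permitted (the general affine subsumes it). A brain-vs-water index
offset can be emulated through the `refractive_index` override; it is off by
default since the resulting axial shift is small relative to the axial PSF.

The steering-efficiency model is separable and linear in |x|, |y|, |z|
(config-selectable bilinear variant with cross terms), fitted by least
squares on ≥ 5 spanning points and normalized to 1 at the origin, clamped to
(0, 1] at evaluation. Weight compensation divides Aᵢ by √η so delivered
power Aᵢ²·η is uniform; the integration test drives this through the
propagation oracle with a synthetic η screen and verifies ≤ 5% spread.

## Stimulation scheduling

Spirals are Archimedean and uniform in time by default — constant angular
speed 2π·rotations/T, radius shrinking linearly from diameter/2 to exactly 0
— with a uniform-arc-length re-parameterization available (the rig's true
profile is unknown; both are provided). Sampling adequacy demands ≥ 10
waypoints per rotation; the default command rate is 50 kHz so that the
standard 50-rotation, 16–20 ms spiral is representable (a 10 kHz default
would reject it). Power accounting is kept in relative units where pulse
shape cancels: pulse energy P_ave/f_rep stands in for peak power, and the
per-cell dose is (P_ave/(f_rep·M))². Dose-matched duration changes support
both constant P·T (the single-spike operating points) and constant P²·T
(the modality-comparison protocol). Volumetric rate is
1000/(n_planes·(frame_period + settle)) vol/s; defaults 33.33 ms + 16.67 ms
reproduce the 6.67 vol/s three-plane operating point.

## Artifact model and removal

One laser pulse contaminates one imaging pixel (femtosecond pulse,
~120 ns pixel dwell, nanosecond fluorescence lifetime). Along a scan line
pulses recur every pixel_rate/f_rep pixels; for a resonant scanner the
spacing in image pixels is modulated by the local mirror speed — minimal at
the line center and diverging toward the turnaround edges (cosine profile,
capped at the line length). The synthetic generator places pulses by
inverting the cumulative pulse-density integral, so generator and detector
share one physical model.

Detection stage 1 estimates per-pixel clean mean and SD from 5 frames before
and 5 after each stimulation interval, per plane, and flags pixels above the
mean by k_sigma = 3 standard deviations. With only ~10 reference frames a
naive mean + 3·SD threshold fires several times more often than the nominal
Gaussian rate, so the multiplier is converted through the Student-t quantile
that preserves the nominal significance — "3 sigma" means the same false
rate regardless of reference count. Stage 2 keeps a candidate only if its
run along the scan line is no wider than the expected compromised width
(1 pixel), its vertical run is a short stack (≤ 3: independent hits on one
column in consecutive lines occur with probability 1/spacing per line), and
the gap to an adjacent run integrates to one interpulse interval within
±50%. A uniformly elevated frame has no narrow runs and yields an empty
mask — the cue to delete frames instead. Because reference frames bracket
the stimulation, evoked transients (present both during and after) inflate
the local SD and are largely self-excluded from candidacy.

Inpainting replaces each contaminated pixel with its nearest clean neighbor
along the scan line (ties average both sides), falling back to the column
for fully contaminated lines; unmasked pixels are never touched, and the
operation is idempotent for a fixed mask since donors are always unmasked.
Frame deletion preserves surviving timestamps (downstream analysis sees an
irregular grid) and warns when an interval spans more than one frame per
plane.

## Response analysis

Evoked responses are (mean F during stimulation − baseline)/baseline with a
1 s baseline ending at onset (0.5–2 s is conventional; 1 s balances noise
against slow drift). A post-stimulation window option (first 1 s after
offset) exists as the artifact-free fallback. Events require the deconvolved
signal AND the ΔF/F first derivative to exceed their own full-trace means by
2 SD — the derivative's own statistics, not the trace's — making detection
invariant under positive affine rescaling. The AR(1)-inverse deconvolution
stand-in max(0, x_t − e^(−Δt/τ)·x_{t−1}) collapses a matched-τ exponential
transient to a single onset sample; any upstream deconvolution can replace
it. A cell with no event in any trial's stimulation window is a
non-responder (attributed to poor opsin expression) and excluded from rate
statistics. Nonspecific activation is binned (10 µm default) by 3D distance
to the nearest target, normalized to the mean targeted response, with the
half-response distance interpolated from the curve anchored at (0, 1);
empty bins are reported missing, not zero. Orientation selectivity is
|(ΔF/F₉₀ − ΔF/F₀)/(ΔF/F₉₀ + ΔF/F₀)| with the sign giving the preference; a
zero denominator is flagged undefined. Condition comparisons are per-ROI
two-sample t-tests.

## Synthetic data

The generator emulates the experimental structure: somata placed by
Poisson-disk sampling (15 µm minimum spacing) in a 480×480×150 µm volume
(tests of the three-plane protocol use 240×240×100 µm), plane-sequential
imaging at 6.67 vol/s (33.33 ms frames + 16.67 ms settle), targeted cells
responding per trial with probability 0.82 except a permanently silent 8%,
non-targeted cells responding with probability 0.82·exp(−d/15 µm) of the
nearest-target distance (half-response ≈ 10 µm, comfortably inside the
25 µm confinement bound), difference-of-exponentials calcium transients
(rise 0.2 s, decay 1.5 s, GCaMP6-like), Gaussian sensor noise, and the
additive mesh artifact in stimulation frames. Rendering uses Gaussian soma
profiles (σ = radius/2) at ~1.9 µm/pixel, matching the scale at which a
512-pixel line spans a cortical field of view.

What it does **not** emulate: light scattering, brain motion, neuropil and
out-of-focus contamination, spontaneous activity, photobleaching, opsin
kinetics, or CNMF source-separation errors. Passing tests therefore
demonstrate correctness of the algorithms under the stated signal model,
not robustness to every in vivo nuisance; the artifact detector's
precision/recall and the chain's rate recovery should be read in that
light.

All generators are bit-reproducible from a seed and emit complete ground
truth (clean movie, artifact mask, per-trial response draws, silent set).

## Problem sizes

Default test and acceptance runs use: 512² SLM grids padded ×2 for
propagation; 12–100 targets for oracle-equivalence checks with z sampled at
1 µm near each focus; movies of 128² pixels, 3 planes, 6–10 trials, 25–60
cells. These sizes keep full-suite runs to a few minutes while leaving every
measured quantity well inside its statistical tolerance; all are parameters,
and larger volumes only cost time.

## Known limitations

* Phase-only superposition gives ~5–10% per-focus power spread for dense
  target sets; a weighted-GS refinement loop would tighten this but is not
  implemented.
* The resonant-scan artifact spacing uses an idealized cosine velocity
  profile; real scanners deviate near the turnarounds, where the model caps
  the spacing at the line length.
* The efficiency model is first-order (separable linear in distance); real
  SLM steering efficiency has a sinc²-shaped falloff that the bilinear
  variant only partially captures.
* `roi_fluorescence` is a fixed-footprint extractor for synthetic movies,
  not a substitute for proper source extraction on real data.
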