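# holostim

A toolkit for 3D holographic two-photon photostimulation combined with
volumetric calcium imaging — the "all-optical" read/write approach to neural
circuits. It covers the computational core of such a system end to end:

* **Hologram synthesis.** A spatial light modulator (SLM) conjugate to the
  objective pupil splits the photostimulation beam into one beamlet per
  targeted neuron. The multi-target phase pattern is the phase of a
  superposition of single-focus fields,

  ```
  φ(u,v) = arg Σᵢ Aᵢ · exp(2πj [xᵢu + yᵢv + Z₂⁰(u,v)C₂⁰(zᵢ) + Z₄⁰(u,v)C₄⁰(zᵢ) + Z₆⁰(u,v)C₆⁰(zᵢ)])
  ```

  where (xᵢ, yᵢ, zᵢ) are cell-body centroids in µm, Aᵢ field-amplitude
  weights, and the Zernike defocus/spherical-aberration coefficients
  C₂ₘ⁰(z) ∝ n·k·z·sin²ᵐα are the Zernike expansion of the exact high-NA
  defocus phase (n·z/λ)·√(1 − sin²α·ρ²). An iterative multi-plane
  Gerchberg–Saxton route handles arbitrary per-plane intensity targets
  (e.g. soma-sized disks) with the same aberration-compensated kernel.
* **Propagation oracle.** Debye/angular-spectrum simulation of the 3D
  two-photon focal field (`exp(j·k_z·z)` with the exact nonparaxial k_z),
  focus detection, PSF metrics, and targeting-error statistics — the ground
  truth every synthesized hologram is checked against.
* **Calibration.** Per-depth 2D affine registration between SLM and imaging
  coordinates (linearly interpolated between 25 µm calibration planes) and a
  linear diffraction-efficiency model η(x,y,z) whose inverse square root
  rebalances target weights.
* **Stimulation scheduling.** Inward spiral scans (~12 µm outer diameter,
  8–50 rotations), repeat schedules, volumetric imaging timing, and the
  laser power budget: with average power P_ave split over M targets at
  repetition rate f_rep, the per-cell two-photon dose scales as
  (P_ave/(f_rep·M))², which is why a low-repetition-rate amplifier can drive
  80+ cells at a few mW per cell.
* **Artifact removal.** The photostimulation laser excites the calcium
  indicator directly, imprinting a periodic "mesh" of bright pixels (one per
  laser pulse, spaced `pixel_rate/f_rep` pixels apart, modulated by resonant
  scanner speed). A two-stage detector (statistical candidates → run-geometry
  gate) marks contaminated pixels for scan-line inpainting; very short
  stimulations can drop whole frames instead.
* **Response analysis.** Stimulation-evoked ΔF/F, binary event detection
  (deconvolved signal AND ΔF/F derivative, both at mean + 2 SD),
  responder/non-responder classification, ensemble response rates,
  nonspecific activation vs distance to the nearest target, two-orientation
  selectivity, and per-ROI condition comparisons.
* **Synthetic data.** A generator for multi-plane GCaMP-like movies with
  stimulation-locked transients, distance-dependent nonspecific activation,
  silent cells, noise, and the mesh artifact — with complete ground truth,
  so every pipeline stage is testable without microscope data.

## Worked example

Write a three-target list and synthesize + verify a hologram from the shell
(`holostim --help` lists all subcommands):

```bash
$ holostim holo demo_targets.csv --simulate --out demo_mask.tiff
wrote demo_mask.tiff (3 targets, superposition)
{
  "n_foci": 3,
  "lateral_error_um": 0.08596985075879997,
  "axial_error_um": 0.005252425467760765,
  "unmatched_targets": []
}
```

The simulated field contains exactly the three requested foci; mean lateral
and axial placement errors (0.086 µm and 0.005 µm) are far below a cell
body's radius, so each beamlet lands on its soma.

```bash
$ holostim simulate --out demo_stack.tiff
axial two-photon FWHM: 14.16 um (NA 0.35)
```

That is the axial confinement of a single beamlet: the two-photon
(squared-intensity) axial profile of the NA 0.35 excitation focus has a full
width at half maximum of ~14 µm, enough to keep stimulation on one cortical
cell layer while addressing a 300 µm depth range.

```bash
$ holostim plan --out demo_plan.json
total duration 2.800 s, 3.6 mW/cell
```

The default plan — 175 back-to-back 16 ms spirals at 300 mW split over 83
targets — lasts 2.8 s and spends 3.6 mW of average power per cell.

The same operations are available as a library:

```python
import numpy as np
from holostim import (OpticalConfig, TargetSet, superposition_hologram,
                      propagate_focal_stack, find_foci)

optics = OpticalConfig()                      # NA 0.35, 1040 nm, water
targets = TargetSet([[30, -40, 25], [-60, 10, -50], [0, 80, 0]])
mask = superposition_hologram(targets, optics)
stack = propagate_focal_stack(mask, optics, z_planes=np.arange(-55, 31, 1.0))
print(len(find_foci(stack, min_separation=10, rel_threshold=0.2)))  # -> 3
```

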