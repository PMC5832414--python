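"""SLM phase-hologram synthesis for 3D multi-target two-photon photostimulation.

The spatial light modulator (SLM) sits in a plane conjugate to the objective
pupil.  A phase-only pattern ``phi(u, v)`` written on the SLM splits the
photostimulation beam into beamlets, one per targeted neuron.  Lateral
displacement of a focus is a linear phase ramp (the Fourier shift theorem);
axial displacement is a defocus term expressed in Zernike polynomials with
first- and second-order spherical-aberration compensation for focusing
through an immersion medium of index ``n``.

Two synthesis routes are provided:

* :func:`superposition_hologram` — the complex sum of single-target fields,
  ``phase{sum_i A_i exp(2*pi*j*[x_i u + y_i v + defocus_waves(z_i)])}``.
* :func:`gs3d_hologram` — iterative multi-plane Gerchberg–Saxton phase
  retrieval against arbitrary per-plane target amplitude images, using the
  same aberration-compensated defocus kernel.

Coordinates: ``u, v`` are physical spatial frequencies in cycles/um spanning
the pupil (``|u| <= u_max = NA / wavelength``), so the tilt term ``2*pi*x*u``
is an exact Fourier shift in microns.  Zernike polynomials are evaluated on
the unit pupil disk ``rho = sqrt(u^2+v^2) / u_max``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

logger = logging.getLogger("holostim")

TWO_PI = 2.0 * np.pi

#: characterized axial addressing range of the SLM (um); beyond it the
#: truncated spherical-aberration series degrades and a warning is logged.
AXIAL_RANGE_UM = 300.0


# ---------------------------------------------------------------------------
# configuration and basic containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the photostimulation path.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength in um (default 1.04, red-shifted opsin excitation).
    refractive_index : float
        Immersion/sample refractive index ``n`` (default 1.33, water).
    na : float
        Numerical aperture ``n*sin(alpha)`` of the excitation cone
        (default 0.35, set by the post-SLM galvo mirror size).
    effective_na : float or None
        NA used inside the Zernike defocus coefficients only.  Tuning this
        knob matches the commanded defocus to the realized focal shift; when
        None the physical ``na`` is used.
    slm_pixels : int
        SLM side length in pixels (default 512).
    slm_pitch_mm : float
        SLM pixel pitch in mm (default 7.68/512 for a 7.68 mm active area).
    zeroth_order_fraction : float
        Fraction of the field left unmodulated by the SLM (imperfect
        diffraction efficiency).  Zero by default.
    zero_block_radius_um : float
        Radius of the zeroth-order beam block in the intermediate focal
        plane, expressed at the sample (default 5 um); only applied when
        ``zero_block`` is set.
    illumination : str
        Pupil amplitude profile: ``"uniform"`` (flat-top, default) or
        ``"gaussian"`` (1/e^2 waist at the pupil edge).
    """

    wavelength: float = 1.04
    refractive_index: float = 1.33
    na: float = 0.35
    effective_na: float | None = None
    slm_pixels: int = 512
    slm_pitch_mm: float = 7.68 / 512
    zeroth_order_fraction: float = 0.0
    zero_block: bool = False
    zero_block_radius_um: float = 5.0
    illumination: str = "uniform"

    def __post_init__(self) -> None:
        if not (0.0 < self.na < self.refractive_index):
            raise ValueError(
                f"NA must satisfy 0 < NA < n; got NA={self.na}, n={self.refractive_index}"
            )
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.slm_pixels < 32:
            raise ValueError("slm_pixels must be >= 32")
        if self.effective_na is not None and self.effective_na <= 0:
            raise ValueError("effective_na must be positive")
        if self.illumination not in ("uniform", "gaussian"):
            raise ValueError(f"unknown illumination {self.illumination!r}")

    @property
    def u_max(self) -> float:
        """Pupil radius as a spatial frequency, NA/wavelength (cycles/um)."""
        return self.na / self.wavelength

    @property
    def na_eff(self) -> float:
        return self.na if self.effective_na is None else self.effective_na

    @property
    def sin_alpha(self) -> float:
        """sin(alpha) of the marginal ray using the effective NA."""
        return self.na_eff / self.refractive_index

    @property
    def wavenumber(self) -> float:
        """k = 2*pi/wavelength (rad/um)."""
        return TWO_PI / self.wavelength

    def pupil_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered 1D spatial-frequency axes (cycles/um) of the SLM grid.

        The SLM grid spans the pupil diameter: sample spacing
        ``du = 2*u_max/slm_pixels``, coordinates ``(idx - N//2)*du``.
        """
        n = self.slm_pixels
        du = 2.0 * self.u_max / n
        ax = (np.arange(n) - n // 2) * du
        return ax, ax

    @property
    def frequency_step(self) -> float:
        return 2.0 * self.u_max / self.slm_pixels

    @property
    def addressable_radius_um(self) -> float:
        """Nyquist limit on lateral displacement for the SLM sampling.

        A tilt of x um advances the phase by ``2*pi*x*du`` per SLM sample;
        aliasing-free addressing requires ``|x| <= 1/(2*du) = N/(4*u_max)``.
        """
        return 1.0 / (2.0 * self.frequency_step)


@dataclass
class TargetSet:
    """3D photostimulation targets in sample coordinates.

    ``positions`` is an (M, 3) array of (x, y, z) in um — origin at the
    center of the field of view on the nominal focal plane, z positive
    deeper into the sample.  ``weights`` are the per-target field amplitudes
    A_i (delivered power scales with A_i^2).
    """

    positions: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (M, 3) array of x, y, z in um")
        if self.positions.shape[0] < 1:
            raise ValueError("at least one target is required")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("target coordinates must be finite")
        if self.weights is None:
            self.weights = np.ones(len(self.positions))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.positions),):
            raise ValueError("weights must have one entry per target")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be nonnegative with at least one positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]


@dataclass
class PhaseMask:
    """Phase-only SLM pattern, radians in [0, 2*pi).

    ``u`` and ``v`` are the 1D spatial-frequency axes (cycles/um) linking
    pixel (row=q over v, col=p over u) to pupil coordinates; ``pupil_radius``
    is u_max.  ``meta`` carries synthesis provenance (e.g. the per-iteration
    Gerchberg–Saxton correlation trace).
    """

    phase: np.ndarray
    u: np.ndarray
    v: np.ndarray
    pupil_radius: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2 or self.phase.shape[0] != self.phase.shape[1]:
            raise ValueError("phase must be a square 2D array")
        if self.phase.shape != (len(self.v), len(self.u)):
            raise ValueError("phase shape must match the (v, u) grid")
        if np.any(self.phase < 0) or np.any(self.phase >= TWO_PI):
            raise ValueError("phase values must lie in [0, 2*pi)")

    @property
    def n(self) -> int:
        return self.phase.shape[0]

    @property
    def du(self) -> float:
        return float(self.u[1] - self.u[0])

    def pupil_mask(self) -> np.ndarray:
        uu, vv = np.meshgrid(self.u, self.v)
        return uu * uu + vv * vv <= self.pupil_radius**2 * (1 + 1e-12)

    def field(self, illumination: str = "uniform") -> np.ndarray:
        """Complex pupil field exp(j*phase) under the given illumination,
        zero outside the pupil disk."""
        disk = self.pupil_mask()
        amp = disk.astype(float)
        if illumination == "gaussian":
            uu, vv = np.meshgrid(self.u, self.v)
            rho2 = (uu * uu + vv * vv) / self.pupil_radius**2
            amp = amp * np.exp(-rho2)
        return amp * np.exp(1j * self.phase)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase (radians) into [0, 2*pi)."""
    out = np.mod(phi, TWO_PI)
    # mod can return 2*pi for inputs just below a multiple of 2*pi
    out[out >= TWO_PI] = 0.0
    return out


# ---------------------------------------------------------------------------
# Zernike defocus with spherical-aberration compensation
# ---------------------------------------------------------------------------

def zernike_z20(rho2: np.ndarray) -> np.ndarray:
    """Defocus polynomial Z_2^0 = sqrt(3) * (2*rho^2 - 1)."""
    return np.sqrt(3.0) * (2.0 * rho2 - 1.0)


def zernike_z40(rho2: np.ndarray) -> np.ndarray:
    """First spherical aberration Z_4^0 = sqrt(5) * (6*rho^4 - 6*rho^2 + 1)."""
    return np.sqrt(5.0) * (6.0 * rho2**2 - 6.0 * rho2 + 1.0)


def zernike_z60(rho2: np.ndarray) -> np.ndarray:
    """Second spherical aberration Z_6^0 = sqrt(7) * (20 rho^6 - 30 rho^4 + 12 rho^2 - 1)."""
    return np.sqrt(7.0) * (20.0 * rho2**3 - 30.0 * rho2**2 + 12.0 * rho2 - 1.0)


def defocus_coefficients(z: float, optics: OpticalConfig) -> tuple[float, float, float]:
    """Zernike coefficients (C20, C40, C60) in waves for an axial shift z (um).

    These are the Zernike-basis expansion of the high-NA defocus phase
    ``(n*z/lambda)*sqrt(1 - sin(alpha)^2 * rho^2)`` truncated at the second
    spherical-aberration order; each coefficient is linear in z.  The NA
    inside sin(alpha) is the *effective* NA (a calibration knob).
    """
    n = optics.refractive_index
    k = optics.wavenumber
    s2 = optics.sin_alpha**2
    c20 = n * k * z * s2 / (8.0 * np.pi * np.sqrt(3.0)) * (
        1.0 + s2 / 4.0 + 9.0 * s2**2 / 80.0 + s2**3 / 16.0
    )
    c40 = n * k * z * s2**2 / (96.0 * np.pi * np.sqrt(5.0)) * (
        1.0 + 3.0 * s2 / 4.0 + 15.0 * s2**2 / 28.0
    )
    c60 = n * k * z * s2**3 / (640.0 * np.pi * np.sqrt(7.0)) * (1.0 + 5.0 * s2 / 4.0)
    return c20, c40, c60


def defocus_waves(z: float, optics: OpticalConfig, rho2: np.ndarray) -> np.ndarray:
    """Aberration-compensated defocus in waves: Z20*C20 + Z40*C40 + Z60*C60."""
    c20, c40, c60 = defocus_coefficients(z, optics)
    return (
        zernike_z20(rho2) * c20
        + zernike_z40(rho2) * c40
        + zernike_z60(rho2) * c60
    )


def _pupil_rho2(optics: OpticalConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    u, v = optics.pupil_coords()
    uu, vv = np.meshgrid(u, v)
    rho2 = (uu * uu + vv * vv) / optics.u_max**2
    disk = rho2 <= 1.0 + 1e-12
    return uu, vv, rho2, disk


def zernike_defocus_phase(z: float, optics: OpticalConfig) -> PhaseMask:
    """Phase mask that shifts the focus axially by z um.

    Returns ``2*pi*(Z20*C20(z) + Z40*C40(z) + Z60*C60(z))`` wrapped to
    [0, 2*pi); the unwrapped phase is linear in z.  Pixels outside the unit
    pupil are zero.
    """
    if abs(z) > AXIAL_RANGE_UM:
        logger.warning(
            "defocus %.1f um exceeds the characterized +/-%.0f um range; "
            "the truncated aberration series may be inaccurate", z, AXIAL_RANGE_UM
        )
    u, v = optics.pupil_coords()
    _, _, rho2, disk = _pupil_rho2(optics)
    phi = np.where(disk, wrap_phase(TWO_PI * defocus_waves(z, optics, rho2)), 0.0)
    return PhaseMask(phi, u, v, optics.u_max)


# ---------------------------------------------------------------------------
# superposition hologram
# ---------------------------------------------------------------------------

def _check_addressable(targets: TargetSet, optics: OpticalConfig) -> None:
    r = optics.addressable_radius_um
    bad = np.where((np.abs(targets.x) > r) | (np.abs(targets.y) > r))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"target {i} at (x={targets.x[i]:.1f}, y={targets.y[i]:.1f}) um is outside "
            f"the addressable range +/-{r:.1f} um set by the SLM Nyquist limit"
        )
    deep = np.where(np.abs(targets.z) > AXIAL_RANGE_UM)[0]
    if deep.size:
        logger.warning(
            "%d target(s) beyond the characterized axial range +/-%.0f um",
            deep.size, AXIAL_RANGE_UM,
        )


def superposition_hologram(targets: TargetSet, optics: OpticalConfig) -> PhaseMask:
    """Multi-target hologram as the phase of a sum of single-focus fields.

    phi(u, v) = phase{ sum_i A_i * exp(2*pi*j * [x_i*u + y_i*v
                        + Z20*C20(z_i) + Z40*C40(z_i) + Z60*C60(z_i)]) }

    Deterministic; pixels outside the unit pupil are set to zero.  Raises
    a range error naming the first target outside the addressable field.
    """
    _check_addressable(targets, optics)
    u, v = optics.pupil_coords()
    uu, vv, rho2, disk = _pupil_rho2(optics)
    total = np.zeros(uu.shape, dtype=complex)
    for (x, y, z), a in zip(targets.positions, targets.weights):
        waves = x * uu + y * vv + defocus_waves(z, optics, rho2)
        total += a * np.exp(TWO_PI * 1j * waves)
    phi = np.where(disk, wrap_phase(np.angle(total)), 0.0)
    return PhaseMask(phi, u, v, optics.u_max)


# ---------------------------------------------------------------------------
# 3D Gerchberg-Saxton
# ---------------------------------------------------------------------------

def gs_target_coords(optics: OpticalConfig) -> np.ndarray:
    """Sample-plane coordinate axis (um) of the GS conjugate grid.

    The FFT of the SLM grid yields sample pixels of size ``1/(N*du)
    = 1/(2*u_max)`` um over a field of ``N/(2*u_max)`` um.
    """
    n = optics.slm_pixels
    dx = 1.0 / (n * optics.frequency_step)
    return (np.arange(n) - n // 2) * dx


def disk_target(
    optics: OpticalConfig,
    center_um: tuple[float, float] = (0.0, 0.0),
    diameter_um: float = 12.0,
) -> np.ndarray:
    """Binary disk amplitude image on the GS grid (e.g. a soma-sized,
    ~12 um scanless excitation disk)."""
    ax = gs_target_coords(optics)
    xx, yy = np.meshgrid(ax, ax)
    r2 = (xx - center_um[0]) ** 2 + (yy - center_um[1]) ** 2
    return (r2 <= (diameter_um / 2.0) ** 2).astype(float)


def _cfft2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def _cifft2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x), norm="ortho"))


def gs3d_hologram(
    target_amplitudes: Sequence[np.ndarray],
    plane_depths: Sequence[float],
    optics: OpticalConfig,
    iterations: int = 50,
    seed: int = 0,
    stop_tol: float = 1e-4,
) -> PhaseMask:
    """Multi-plane Gerchberg-Saxton hologram with aberration-compensated defocus.

    Each iteration propagates the pupil field to every target plane with the
    defocus kernel of :func:`zernike_defocus_phase`, replaces the amplitude
    by the target while keeping the phase, back-propagates, sums the pupil
    fields over planes, and re-imposes the uniform (or Gaussian) pupil
    amplitude.  The initial phase is uniform random from ``seed``; iteration
    stops early when the two-photon target correlation changes by less than
    ``stop_tol``.  The per-iteration correlation trace is stored in
    ``mask.meta['gs_correlation']``.

    ``target_amplitudes`` are nonnegative images on the GS conjugate grid
    (see :func:`gs_target_coords`), one per entry of ``plane_depths``.
    """
    if len(target_amplitudes) < 1 or len(target_amplitudes) != len(plane_depths):
        raise ValueError("need >= 1 target plane, one amplitude image per depth")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = optics.slm_pixels
    targets = []
    for amp in target_amplitudes:
        amp = np.asarray(amp, dtype=float)
        if amp.shape != (n, n):
            raise ValueError(f"target amplitude must be {n}x{n} (the GS grid)")
        if np.any(amp < 0):
            raise ValueError("target amplitudes must be nonnegative")
        targets.append(amp)
    if not any(np.any(t > 0) for t in targets):
        raise ValueError("all-zero target amplitude")

    _, _, rho2, disk = _pupil_rho2(optics)
    u, v = optics.pupil_coords()
    amp0 = disk.astype(float)
    if optics.illumination == "gaussian":
        amp0 = amp0 * np.exp(-rho2)
    amp0 /= np.linalg.norm(amp0)
    kernels = [np.exp(TWO_PI * 1j * defocus_waves(z, optics, rho2)) * disk
               for z in plane_depths]

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, TWO_PI, size=(n, n))
    pupil = amp0 * np.exp(1j * phase)

    tgt2 = np.concatenate([(t**2).ravel() for t in targets])
    correlations: list[float] = []
    for _ in range(iterations):
        back = np.zeros((n, n), dtype=complex)
        sim2 = []
        for kern, tgt in zip(kernels, targets):
            focal = _cfft2(pupil * kern)
            sim2.append((np.abs(focal) ** 2).ravel())
            constrained = tgt * np.exp(1j * np.angle(focal))
            back += _cifft2(constrained) * np.conj(kern)
        sim2 = np.concatenate(sim2)
        # two-photon correlation between simulated and requested intensity
        c = float(np.corrcoef(sim2**2, tgt2**2)[0, 1]) if np.ptp(tgt2) > 0 else 0.0
        correlations.append(c)
        pupil = amp0 * np.exp(1j * np.angle(back))
        if len(correlations) >= 2 and abs(correlations[-1] - correlations[-2]) < stop_tol:
            break

    phi = np.where(disk, wrap_phase(np.angle(pupil)), 0.0)
    # angle() of exactly-zero pixels is 0, already consistent with the disk fill
    return PhaseMask(phi, u, v, optics.u_max, meta={"gs_correlation": correlations})


# ---------------------------------------------------------------------------
# diffraction-efficiency compensation
# ---------------------------------------------------------------------------

class SupportsEfficiency(Protocol):
    def efficiency(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray: ...


def compensate_efficiency(targets: TargetSet, model: SupportsEfficiency) -> TargetSet:
    """Rescale target weights so delivered power is uniform across the field.

    The SLM's steering efficiency eta(x, y, z) drops with deflection angle;
    delivered power at a target scales with A_i^2 * eta.  Setting
    ``A_i' = A_i / sqrt(eta_i)`` equalizes it while preserving the relative
    ordering of requested powers.
    """
    eta = np.asarray(model.efficiency(targets.x, targets.y, targets.z), dtype=float)
    if np.any(eta <= 0):
        i = int(np.argmin(eta))
        raise ValueError(
            f"efficiency model is non-positive ({eta[i]:.3g}) at target {i}; "
            "cannot compensate"
        )
    return replace(targets, weights=targets.weights / np.sqrt(eta))
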