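"""Spiral-scan trajectories, stimulation schedules, and the laser power budget.

In the hybrid photostimulation scheme the SLM splits the beam into one
beamlet per targeted cell and a pair of post-SLM galvanometers spirally
scans all beamlets over the cell bodies simultaneously (~12 um outer spiral
diameter, 8-50 rotations with progressively shrinking radius; spirals are
repeated back-to-back to build longer stimuli).

Power budget: average power P_ave = P_peak * f_rep * (pulse-shape constant),
and the beam is split M ways, so the per-cell two-photon excitation scales
with (P_peak / M)^2 = (P_ave / (f_rep * M))^2 up to constants.  Lowering the
repetition rate raises peak power at fixed average power — the key trick
that lets a fixed thermal budget drive ~80+ cells at once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

#: default galvo command rate (Hz); high enough to sample the standard
#: 50-rotation spiral at >= 10 points per turn even at 16-20 ms durations
DEFAULT_SAMPLE_RATE_HZ = 50_000.0


@dataclass
class SpiralScan:
    """An inward Archimedean spiral: r(t) = R*(1 - t/T), theta = 2*pi*N*t/T."""

    outer_diameter: float  # um
    rotations: int
    duration_ms: float
    sample_rate_hz: float
    waypoints: np.ndarray  # (n, 2) x/y offsets in um

    def __post_init__(self) -> None:
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        r = np.hypot(self.waypoints[:, 0], self.waypoints[:, 1])
        if self.rotations < 1:
            raise ValueError("rotations must be >= 1")
        if np.any(np.diff(r) > 1e-9):
            raise ValueError("spiral radius must be non-increasing")
        if abs(r[0] - self.outer_diameter / 2.0) > 1e-9:
            raise ValueError("spiral must start at the outer radius")


def spiral_trajectory(
    diameter: float = 12.0,
    rotations: int = 50,
    duration_ms: float = 20.0,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    parameterization: str = "uniform_time",
) -> SpiralScan:
    """Galvo waypoints for one inward spiral scan.

    ``uniform_time`` (default) samples the Archimedean spiral uniformly in
    time, giving constant angular speed 2*pi*rotations/T and a linearly
    shrinking radius from diameter/2 to 0.  ``uniform_arc`` re-parameterizes
    to constant speed along the arc.  Raises if the command rate undersamples
    the spiral (< 10 samples per rotation).
    """
    if duration_ms <= 0 or diameter <= 0:
        raise ValueError("diameter and duration must be positive")
    if rotations < 1:
        raise ValueError("rotations must be >= 1")
    n_samples = int(round(sample_rate_hz * duration_ms / 1000.0))
    if n_samples < 10 * rotations:
        needed = 10 * rotations * 1000.0 / duration_ms
        raise ValueError(
            f"sample rate {sample_rate_hz:g} Hz undersamples {rotations} rotations "
            f"in {duration_ms:g} ms; need >= {needed:g} Hz"
        )
    tau = np.linspace(0.0, 1.0, n_samples + 1)  # include both endpoints
    radius = diameter / 2.0
    if parameterization == "uniform_arc":
        # invert the cumulative arc length of the uniform-time spiral
        dense = np.linspace(0.0, 1.0, 20 * n_samples + 1)
        r = radius * (1.0 - dense)
        th = 2.0 * np.pi * rotations * dense
        x = r * np.cos(th)
        y = r * np.sin(th)
        s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
        tau = np.interp(np.linspace(0.0, s[-1], n_samples + 1), s, dense)
    elif parameterization != "uniform_time":
        raise ValueError(f"unknown parameterization {parameterization!r}")
    r = radius * (1.0 - tau)
    theta = 2.0 * np.pi * rotations * tau
    waypoints = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    waypoints[-1] = 0.0  # exact center endpoint
    return SpiralScan(diameter, rotations, duration_ms, sample_rate_hz, waypoints)


def repeat_schedule(per_scan_duration_ms: float, repeats: int) -> float:
    """Total stimulation duration in seconds of back-to-back repeated spirals."""
    if per_scan_duration_ms <= 0 or repeats <= 0:
        raise ValueError("duration and repeats must be positive")
    return per_scan_duration_ms * repeats / 1000.0


@dataclass(frozen=True)
class LaserConfig:
    """Photostimulation laser operating point."""

    rep_rate_hz: float = 1e6
    average_power_mw: float = 300.0
    n_targets: int = 1

    def __post_init__(self) -> None:
        if self.rep_rate_hz <= 0:
            raise ValueError("repetition rate must be positive")
        if self.average_power_mw < 0:
            raise ValueError("average power must be nonnegative")
        if self.n_targets < 1:
            raise ValueError("need at least one target (M >= 1)")


@dataclass(frozen=True)
class PowerBudget:
    """Per-target power accounting; ``relative_dose`` is in relative units
    (up to a pulse-shape constant) and scales as (P_peak/M)^2."""

    per_cell_average_mw: float
    peak_power_total: float  # P_ave / f_rep: pulse energy, proportional to P_peak
    relative_dose: float


def power_budget(laser: LaserConfig) -> PowerBudget:
    """Split the laser budget over M beamlets.

    per-cell average power = P_ave / M; the two-photon dose per cell scales
    with (P_peak / M)^2 = (P_ave / (f_rep * M))^2, so halving f_rep at fixed
    average power quadruples the dose, and doubling M quarters it.
    """
    p_peak = laser.average_power_mw / laser.rep_rate_hz
    return PowerBudget(
        per_cell_average_mw=laser.average_power_mw / laser.n_targets,
        peak_power_total=p_peak,
        relative_dose=(p_peak / laser.n_targets) ** 2,
    )


def equal_dose_power(
    ref_duration_ms: float,
    ref_power_mw: float,
    new_duration_ms: float,
    mode: str = "constant_energy",
) -> float:
    """Rescale power when changing stimulation duration at matched dose.

    ``constant_energy`` keeps P*T constant (P' = P*T/T'), matching the
    single-spike operating points (2.25 mW at 20 ms <-> 4.5 mW at 10 ms).
    ``constant_power_sq_time`` keeps P^2*T constant (P' = P*sqrt(T/T')),
    the protocol used when comparing stimulation modalities.
    """
    if min(ref_duration_ms, ref_power_mw, new_duration_ms) <= 0:
        raise ValueError("durations and power must be positive")
    if mode == "constant_energy":
        return ref_power_mw * ref_duration_ms / new_duration_ms
    if mode == "constant_power_sq_time":
        return ref_power_mw * math.sqrt(ref_duration_ms / new_duration_ms)
    raise ValueError(f"unknown mode {mode!r}")


def volumetric_rate(
    n_planes: int,
    frame_period_ms: float = 1000.0 / 30.0,
    settle_wait_ms: float = 16.67,
) -> float:
    """Volume rate (vol/s) of plane-sequential imaging with an ETL.

    Each plane costs one resonant frame (~33.33 ms at the intrinsic 30 fps)
    plus a settle wait (10-17 ms) for the tunable lens:
    rate = 1000 / (n_planes * (frame_period + settle_wait)).
    """
    if n_planes < 1 or frame_period_ms <= 0 or settle_wait_ms < 0:
        raise ValueError("invalid timing parameters")
    return 1000.0 / (n_planes * (frame_period_ms + settle_wait_ms))


def pulses_delivered(duration_ms: float, rep_rate_hz: float) -> int:
    """Number of laser pulses in a stimulation window: floor(T * f_rep)."""
    if duration_ms <= 0 or rep_rate_hz <= 0:
        raise ValueError("duration and repetition rate must be positive")
    return int(math.floor(duration_ms * rep_rate_hz / 1000.0))


@dataclass
class StimPlan:
    """A complete photostimulation plan: spiral, repeats, per-cell power."""

    spiral: SpiralScan
    repeats: int
    laser: LaserConfig

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def total_duration_s(self) -> float:
        return repeat_schedule(self.spiral.duration_ms, self.repeats)

    @property
    def per_cell_power_mw(self) -> float:
        return power_budget(self.laser).per_cell_average_mw

    def to_json(self, path) -> None:
        payload = {
            "spiral": {
                "outer_diameter": self.spiral.outer_diameter,
                "rotations": self.spiral.rotations,
                "duration_ms": self.spiral.duration_ms,
                "sample_rate_hz": self.spiral.sample_rate_hz,
            },
            "repeats": self.repeats,
            "laser": asdict(self.laser),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def from_json(path) -> "StimPlan":
        with open(path) as fh:
            payload = json.load(fh)
        sp = payload["spiral"]
        spiral = spiral_trajectory(
            sp["outer_diameter"], sp["rotations"], sp["duration_ms"], sp["sample_rate_hz"]
        )
        return StimPlan(spiral, payload["repeats"], LaserConfig(**payload["laser"]))
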