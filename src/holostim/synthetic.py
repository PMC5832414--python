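"""Synthetic multi-plane calcium movies and fixtures with full ground truth.

Emulates the structure of the in vivo experiments: GCaMP-labelled somata
scattered through a 480 x 480 x 150 um volume imaged plane-sequentially,
photostimulation trials that evoke exponential-kernel calcium transients in
targeted cells with probability ``p_target`` (a fraction of cells is
permanently silent, as with poor opsin expression), distance-dependent
nonspecific activation of non-targeted cells, Gaussian sensor noise, and a
mesh-grid stimulation artifact whose pixel geometry follows the
pixel-clock / laser-repetition-rate ratio.

Every generator is bit-reproducible under a fixed seed and returns the
complete ground truth (clean movie, artifact mask, per-trial response
labels, cell geometry) so downstream tests never depend on unavailable
truth.  What it does *not* emulate: scattering, motion, neuropil
contamination, spontaneous activity, or opsin kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import Trial
from .artifact import MovieBundle, expected_artifact_spacing
from .calibration import Affine
from .optics import TargetSet


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the emulated experiment.

    Geometry defaults follow the large-scale photostimulation sessions
    (480 x 480 x 150 um imaged volume); response-model defaults follow the
    measured rates (82% targeted response probability, 8% silent cells,
    nonspecific activation confined well inside 25 um).
    """

    bounds_um: tuple[float, float, float] = (480.0, 480.0, 150.0)
    n_cells: int = 60
    min_spacing_um: float = 15.0
    cell_radius_um: float = 6.0
    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.5
    background: float = 50.0
    cell_brightness: float = 100.0
    response_amplitude: float = 1.0  # peak dF/F of an evoked transient
    noise_sigma: float = 3.0
    p_target: float = 0.82
    p0_nonspecific: float = 0.82
    lambda_d_um: float = 15.0
    silent_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_target <= 1 and 0 <= self.p0_nonspecific <= 1
                and 0 <= self.silent_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.rise_tau_s, self.decay_tau_s) <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.min_spacing_um >= float(np.linalg.norm(self.bounds_um)):
            raise ValueError("min spacing exceeds the volume diagonal")


def _poisson_disk(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float],
    min_spacing: float,
    seed_points: np.ndarray | None = None,
    max_tries: int = 20_000,
) -> np.ndarray:
    """Dart-throwing Poisson-disk sampling in a centered box."""
    half = np.asarray(bounds) / 2.0
    pts = [] if seed_points is None else [p for p in seed_points]
    placed = 0
    tries = 0
    while placed < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} points with {min_spacing} um spacing in "
                f"{bounds} after {max_tries} tries; relax the spacing"
            )
        cand = rng.uniform(-half, half)
        tries += 1
        if all(np.linalg.norm(cand - p) >= min_spacing for p in pts):
            pts.append(cand)
            placed += 1
    start = 0 if seed_points is None else len(seed_points)
    return np.asarray(pts[start:])


def make_targets(spec: SceneSpec, m: int, rng: np.random.Generator | None = None) -> TargetSet:
    """Sample M target centroids with Poisson-disk spacing inside the volume."""
    if m < 1:
        raise ValueError("need at least one target")
    if m > spec.n_cells:
        raise ValueError("more targets than cells in the scene")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    return TargetSet(_poisson_disk(rng, m, spec.bounds_um, spec.min_spacing_um))


@dataclass
class MovieTruth:
    """Ground truth emitted alongside every synthetic movie."""

    clean_frames: np.ndarray  # noisy frames without the stimulation artifact
    artifact_mask: np.ndarray  # bool, true at injected mesh pixels
    responded: np.ndarray  # (n_trials, n_cells) evoked-transient flags
    cell_positions: np.ndarray  # (n_cells, 3) um
    cell_planes: np.ndarray  # plane index per cell
    cell_px: np.ndarray  # (n_cells, 2) x, y pixel centers
    targeted: np.ndarray  # cell indices carrying a beamlet
    silent: np.ndarray  # targeted cells that never respond
    trials: list[Trial] = field(default_factory=list)
    plane_depths: np.ndarray | None = None
    um_per_px: float = 1.0
    dff_true: np.ndarray | None = None  # (n_cells, n_frames_per_plane)


def _transient_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalized."""
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise)) * np.exp(-np.maximum(t, 0) / decay), 0.0)
    t_pk = rise * np.log1p(decay / rise)
    pk = (1.0 - np.exp(-t_pk / rise)) * np.exp(-t_pk / decay)
    return k / pk


def _mesh_columns(rng, width: int, pixel_rate: float, f_rep: float, scan_model: str) -> list[np.ndarray]:
    """Artifact column positions per row for one frame.

    Laser pulses arrive uniformly in time, so along a scan line one pulse
    lands per unit of integrated pulse density 1/spacing(column); pulse k of
    a line sits where the cumulative density crosses (phase + k).  The line
    phase advances by a random flyback remainder between rows.
    """
    cols = np.arange(width)
    if scan_model == "linear":
        spacing = np.full(width, expected_artifact_spacing(pixel_rate, f_rep, "linear"))
    else:
        spacing = expected_artifact_spacing(pixel_rate, f_rep, "resonant", cols, width)
    cum = np.concatenate([[0.0], np.cumsum(1.0 / spacing)])  # pulses up to column edge
    total = cum[-1]
    edges = np.arange(width + 1, dtype=float)
    rows = []
    phase = rng.uniform(0.0, 1.0)
    for _ in range(width):
        # pulse positions: cumulative density equals phase + k, k = 0, 1, ...
        targets_density = phase + np.arange(0.0, total - phase, 1.0)
        x = np.interp(targets_density, cum, edges)
        c = np.unique(np.clip(x.astype(int), 0, width - 1))
        rows.append(c)
        phase = (phase + rng.uniform(0.0, 1.0)) % 1.0
    return rows


def make_movie(
    spec: SceneSpec,
    targets: TargetSet | int,
    n_trials: int = 10,
    n_planes: int = 3,
    fov_px: int = 128,
    frame_period_ms: float = 1000.0 / 30.0,
    settle_ms: float = 16.67,
    stim_duration_s: float = 0.094,
    pre_s: float = 3.0,
    inter_trial_s: float = 5.0,
    pixel_rate_hz: float = 8.2e6,
    stim_rep_rate_hz: float = 1e6,
    scan_model: str = "resonant",
    artifact_amplitude: float = 150.0,
    rng: np.random.Generator | None = None,
) -> tuple[MovieBundle, MovieTruth]:
    """Render a multi-plane movie with stimulation-locked responses.

    ``targets`` is either a TargetSet (its positions become the first cells
    of the scene) or an integer M to sample targets internally.  Frames are
    acquired plane-sequentially at ``frame_period + settle`` per frame;
    every trial stimulates all targets for ``stim_duration_s`` and injects
    the mesh artifact into the overlapping frames.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if isinstance(targets, int):
        targets = make_targets(spec, targets, rng)
    m = len(targets)
    if m > spec.n_cells:
        raise ValueError("more targets than cells in the scene")
    extra = _poisson_disk(
        rng, spec.n_cells - m, spec.bounds_um, spec.min_spacing_um,
        seed_points=targets.positions,
    )
    cells = np.vstack([targets.positions, extra]) if len(extra) else targets.positions.copy()
    n_cells = len(cells)
    targeted = np.arange(m)

    # plane assignment: evenly spaced planes across the z extent
    zhalf = spec.bounds_um[2] / 2.0
    plane_depths = np.linspace(-zhalf, zhalf, n_planes + 2)[1:-1] if n_planes > 1 else np.array([0.0])
    cell_planes = np.argmin(np.abs(cells[:, 2:3] - plane_depths[None, :]), axis=1)

    um_per_px = spec.bounds_um[0] / fov_px
    cell_px = np.column_stack([
        cells[:, 0] / um_per_px + fov_px / 2.0,
        cells[:, 1] / um_per_px + fov_px / 2.0,
    ])

    # frame schedule
    frame_step_s = (frame_period_ms + settle_ms) / 1000.0
    total_s = pre_s + n_trials * (stim_duration_s + inter_trial_s)
    n_frames = int(np.ceil(total_s / frame_step_s / n_planes)) * n_planes
    timestamps = np.arange(n_frames) * frame_step_s
    plane_index = np.arange(n_frames) % n_planes

    # trials and response draws
    trial_period = stim_duration_s + inter_trial_s
    trials = []
    responded = np.zeros((n_trials, n_cells), dtype=bool)
    n_silent = int(round(spec.silent_fraction * m))
    silent = targeted[rng.permutation(m)[:n_silent]] if n_silent else np.array([], dtype=int)
    d_nearest = np.min(
        np.linalg.norm(cells[:, None, :] - targets.positions[None, :, :], axis=2), axis=1
    )
    p_cell = np.where(
        np.isin(np.arange(n_cells), targeted),
        spec.p_target,
        spec.p0_nonspecific * np.exp(-d_nearest / spec.lambda_d_um),
    )
    p_cell[silent] = 0.0
    for i in range(n_trials):
        s = pre_s + i * trial_period
        trials.append(Trial(0, i, s, s + stim_duration_s, tuple(int(t) for t in targeted)))
        responded[i] = rng.random(n_cells) < p_cell

    # per-cell dF/F on the per-plane time grid
    plane_t = timestamps[plane_index == 0]  # same cadence for every plane
    dff_true = np.zeros((n_cells, len(plane_t)))
    for i, tr in enumerate(trials):
        kern = _transient_kernel(plane_t - tr.stim_start, spec.rise_tau_s, spec.decay_tau_s)
        dff_true[responded[i]] += spec.response_amplitude * kern[None, :]

    # render footprints per plane, then frames
    h = w = fov_px
    yy, xx = np.mgrid[0:h, 0:w]
    sigma_px = spec.cell_radius_um / 2.0 / um_per_px
    clean = np.empty((n_frames, h, w))
    for p in range(n_planes):
        sel_cells = np.flatnonzero(cell_planes == p)
        foot = np.zeros((len(sel_cells), h * w))
        for k, ci in enumerate(sel_cells):
            cx, cy = cell_px[ci]
            foot[k] = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)).ravel()
        frames_p = np.flatnonzero(plane_index == p)
        # fluorescence per cell per plane-frame: brightness * (1 + dF/F)
        fvals = spec.cell_brightness * (1.0 + dff_true[sel_cells])
        imgs = spec.background + (fvals.T @ foot).reshape(-1, h, w)
        clean[frames_p] = imgs
    clean += rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    np.clip(clean, 0.0, None, out=clean)

    # stimulation artifact: additive mesh at pulse-locked pixels
    stim_intervals = [(tr.stim_start, tr.stim_end) for tr in trials]
    mask = np.zeros(clean.shape, dtype=bool)
    for s, e in stim_intervals:
        overlap = np.flatnonzero((timestamps < e) & (timestamps + frame_step_s * 0.999 > s))
        for f in overlap:
            for r, cols in enumerate(_mesh_columns(rng, w, pixel_rate_hz, stim_rep_rate_hz, scan_model)):
                mask[f, r, cols] = True
    frames = clean.copy()
    frames[mask] = clean[mask] + artifact_amplitude

    movie = MovieBundle(
        frames, timestamps, plane_index, stim_intervals,
        pixel_rate_hz, stim_rep_rate_hz, scan_model,
    )
    truth = MovieTruth(
        clean_frames=clean, artifact_mask=mask, responded=responded,
        cell_positions=cells, cell_planes=cell_planes, cell_px=cell_px,
        targeted=targeted, silent=silent, trials=trials,
        plane_depths=plane_depths, um_per_px=um_per_px, dff_true=dff_true,
    )
    return movie, truth


def make_calibration_fixture(
    true_affines: list[tuple[float, Affine]],
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid_n: int = 7,
    extent_um: float = 240.0,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Point correspondences for affine calibration: a grid_n x grid_n grid
    over ``extent_um`` squared, forward-mapped through the true per-depth
    affine plus Gaussian localization noise."""
    if noise_sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    ax = np.linspace(-extent_um / 2.0, extent_um / 2.0, grid_n)
    gx, gy = np.meshgrid(ax, ax)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    out = {}
    for depth, aff in true_affines:
        img = aff.apply(grid)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        out[depth] = (grid.copy(), img)
    return out
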