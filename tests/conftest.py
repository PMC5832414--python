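"""Shared fixtures: optical configs and the expensive simulation products
(reused across test modules to keep the suite fast)."""

import numpy as np
import pytest

from holostim.artifact import detect_artifact_pixels, inpaint_artifact
from holostim.optics import OpticalConfig, TargetSet, superposition_hologram
from holostim.propagate import (
    find_foci,
    focus_power,
    propagate_focal_stack,
    targeting_error,
)
from holostim.synthetic import SceneSpec, make_movie


@pytest.fixture(scope="session")
def optics():
    """Photostimulation-path defaults: NA 0.35, 1.04 um, water immersion."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def optics_small():
    """Reduced SLM resolution for fast propagation property tests."""
    return OpticalConfig(slm_pixels=128)


@pytest.fixture(scope="session")
def psf_stack(optics):
    """Unaberrated focal stack: zero-phase pupil, z in [-40, 40] um at 1 um."""
    from holostim.optics import zernike_defocus_phase

    mask = zernike_defocus_phase(0.0, optics)
    zs = np.arange(-40.0, 40.5, 1.0)
    return propagate_focal_stack(mask, optics, zs, fov=40.0)


@pytest.fixture(scope="session")
def multi_target_run(optics):
    """12 weighted targets >= 30 um apart across 240 x 240 x 200 um,
    synthesized by superposition and measured by the propagation oracle."""
    rng = np.random.default_rng(0)
    pos = []
    while len(pos) < 12:
        c = rng.uniform([-120, -120, -100], [120, 120, 100])
        if all(np.linalg.norm(c - p) >= 30 for p in pos):
            pos.append(c)
    pos = np.asarray(pos)
    weights = rng.uniform(0.6, 1.4, len(pos))
    targets = TargetSet(pos, weights)
    mask = superposition_hologram(targets, optics)
    zs = np.unique(np.round(
        np.concatenate([np.arange(z - 3, z + 3.5, 1.0) for z in pos[:, 2]]), 6))
    zs.sort()
    stack = propagate_focal_stack(mask, optics, zs, fov=260)
    foci = find_foci(stack, min_separation=10, rel_threshold=0.05)
    summary = targeting_error(targets, foci)
    powers = np.full(len(pos), np.nan)
    for r, c in summary.matched_pairs:
        powers[r] = focus_power(stack, foci[c])
    return {
        "targets": targets, "mask": mask, "stack": stack, "foci": foci,
        "summary": summary, "powers": powers,
    }


@pytest.fixture(scope="session")
def movie_fixture():
    """Synthetic movie at the imaging conditions of the three-plane
    ensemble experiments (240 x 240 x 100 um, ~1.9 um pixels), with its
    artifact detection and inpainting products."""
    spec = SceneSpec(seed=1, bounds_um=(240.0, 240.0, 100.0), n_cells=60)
    movie, truth = make_movie(spec, 15, n_trials=6, fov_px=128)
    detected = detect_artifact_pixels(movie)
    cleaned = inpaint_artifact(movie, detected)
    return {
        "spec": spec, "movie": movie, "truth": truth,
        "detected": detected, "cleaned": cleaned,
    }


@pytest.fixture(scope="session")
def chain_fixture():
    """Full analysis chain on an independent synthetic session: movie ->
    artifact cleaning -> trace extraction -> events -> response rates."""
    from holostim.analysis import (
        TraceSet,
        deconvolve_stub,
        detect_events,
        dff_from_fluorescence,
        roi_fluorescence,
        trial_event_matrix,
    )

    spec = SceneSpec(seed=5, bounds_um=(240.0, 240.0, 100.0), n_cells=60)
    movie, truth = make_movie(spec, 18, n_trials=10, fov_px=128)
    detected = detect_artifact_pixels(movie)
    cleaned = inpaint_artifact(movie, detected)
    f, ts = roi_fluorescence(
        cleaned.frames, cleaned.plane_index, cleaned.timestamps,
        truth.cell_px, truth.cell_planes, radius_px=2.5,
    )
    dff = dff_from_fluorescence(f)
    dt = float(np.median(np.diff(ts)))
    dec = deconvolve_stub(dff, dt, spec.decay_tau_s)
    traces = TraceSet(truth.cell_positions, dff, ts, dec, truth.trials)
    events = detect_events(traces)
    per_trial = trial_event_matrix(events, ts, truth.trials, pad_s=0.5)
    return {
        "spec": spec, "movie": movie, "truth": truth, "cleaned": cleaned,
        "traces": traces, "events": events, "per_trial": per_trial,
    }
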