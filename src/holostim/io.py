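"""File formats: target lists, optics configs, phase masks, focal stacks,
movies, calibrations, and trace tables.

Phase masks travel as 32-bit float TIFF (radians) with a JSON grid sidecar,
or as 8-bit PNG in the common SLM driver dialect (gray g <-> phase
2*pi*g/256).  Movies live in an HDF5 container of record (frames,
timestamps, plane indices, stimulation intervals in one file) with
multi-page TIFF import/export.  Everything else is CSV/JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .analysis import TraceSet, Trial
from .artifact import MovieBundle
from .optics import TWO_PI, OpticalConfig, PhaseMask, TargetSet
from .propagate import FocalStack

# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

TARGET_COLUMNS = ["x_um", "y_um", "z_um", "weight"]


def save_targets_csv(targets: TargetSet, path) -> None:
    df = pd.DataFrame(targets.positions, columns=TARGET_COLUMNS[:3])
    df["weight"] = targets.weights
    df.to_csv(path, index=False)


def load_targets_csv(path) -> TargetSet:
    df = pd.read_csv(path)
    missing = [c for c in TARGET_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"target CSV missing columns {missing}; expected {TARGET_COLUMNS}")
    weights = df["weight"].to_numpy() if "weight" in df.columns else None
    return TargetSet(df[TARGET_COLUMNS[:3]].to_numpy(), weights)


def save_targets_json(targets: TargetSet, path) -> None:
    payload = [
        {"x_um": x, "y_um": y, "z_um": z, "weight": w}
        for (x, y, z), w in zip(targets.positions.tolist(), targets.weights.tolist())
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_targets_json(path) -> TargetSet:
    payload = json.loads(Path(path).read_text())
    pos = [[t["x_um"], t["y_um"], t["z_um"]] for t in payload]
    weights = [t.get("weight", 1.0) for t in payload]
    return TargetSet(np.asarray(pos), np.asarray(weights))


# ---------------------------------------------------------------------------
# optics config
# ---------------------------------------------------------------------------

def save_optics_yaml(optics: OpticalConfig, path) -> None:
    from dataclasses import asdict

    Path(path).write_text(yaml.safe_dump(asdict(optics), sort_keys=False))


def load_optics_yaml(path) -> OpticalConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(OpticalConfig.__dataclass_fields__)
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown optics keys {sorted(unknown)}; valid: {sorted(valid)}")
    return OpticalConfig(**payload)


# ---------------------------------------------------------------------------
# phase masks
# ---------------------------------------------------------------------------

def _mask_sidecar(mask: PhaseMask) -> dict:
    return {"pupil_radius_cyc_per_um": mask.pupil_radius, "n": mask.n}


def save_phase_tiff(mask: PhaseMask, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.phase.astype(np.float32), photometric="minisblack")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(_mask_sidecar(mask)))


def load_phase_tiff(path) -> PhaseMask:
    path = Path(path)
    phase = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n = phase.shape[0]
    du = 2.0 * meta["pupil_radius_cyc_per_um"] / n
    ax = (np.arange(n) - n // 2) * du
    phase = np.clip(phase, 0.0, np.nextafter(TWO_PI, 0.0))
    return PhaseMask(phase, ax, ax, meta["pupil_radius_cyc_per_um"])


def save_phase_png(mask: PhaseMask, path) -> None:
    """8-bit SLM dialect: gray g = floor(256 * phase / (2*pi)), clamped to 255."""
    g = np.minimum(np.floor(mask.phase / TWO_PI * 256.0), 255.0).astype(np.uint8)
    Image.fromarray(g, mode="L").save(path)
    p = Path(path)
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(_mask_sidecar(mask)))


def load_phase_png(path) -> PhaseMask:
    p = Path(path)
    g = np.asarray(Image.open(p), dtype=float)
    meta = json.loads(p.with_suffix(p.suffix + ".json").read_text())
    n = g.shape[0]
    du = 2.0 * meta["pupil_radius_cyc_per_um"] / n
    ax = (np.arange(n) - n // 2) * du
    return PhaseMask(g / 256.0 * TWO_PI, ax, ax, meta["pupil_radius_cyc_per_um"])


# ---------------------------------------------------------------------------
# focal stacks
# ---------------------------------------------------------------------------

def save_focal_stack(stack: FocalStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.intensity.astype(np.float32), photometric="minisblack")
    meta = {
        "z_planes_um": stack.z_planes.tolist(),
        "dx_um": stack.dx,
        "x0_um": stack.x0,
        "y0_um": stack.y0,
        "photon_order": stack.photon_order,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_focal_stack(path) -> FocalStack:
    path = Path(path)
    inten = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FocalStack(
        inten, np.asarray(meta["z_planes_um"]), meta["dx_um"], meta["x0_um"],
        meta["y0_um"], meta["photon_order"],
    )


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def save_movie_h5(movie: MovieBundle, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=movie.frames.astype(np.float32))
        f.create_dataset("timestamps", data=movie.timestamps)
        f.create_dataset("plane_index", data=movie.plane_index)
        f.create_dataset("stim_intervals", data=np.asarray(movie.stim_intervals, dtype=float).reshape(-1, 2))
        f.attrs["pixel_rate_hz"] = movie.pixel_rate_hz
        f.attrs["stim_rep_rate_hz"] = movie.stim_rep_rate_hz
        f.attrs["scan_model"] = movie.scan_model


def load_movie_h5(path) -> MovieBundle:
    with h5py.File(path, "r") as f:
        return MovieBundle(
            frames=f["frames"][...].astype(float),
            timestamps=f["timestamps"][...],
            plane_index=f["plane_index"][...],
            stim_intervals=[tuple(r) for r in f["stim_intervals"][...]],
            pixel_rate_hz=float(f.attrs["pixel_rate_hz"]),
            stim_rep_rate_hz=float(f.attrs["stim_rep_rate_hz"]),
            scan_model=str(f.attrs["scan_model"]),
        )


def save_movie_tiff(movie: MovieBundle, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "timestamps_s": movie.timestamps.tolist(),
        "plane_index": movie.plane_index.tolist(),
        "stim_intervals_s": [list(i) for i in movie.stim_intervals],
        "pixel_rate_hz": movie.pixel_rate_hz,
        "stim_rep_rate_hz": movie.stim_rep_rate_hz,
        "scan_model": movie.scan_model,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_movie_tiff(path) -> MovieBundle:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return MovieBundle(
        frames, np.asarray(meta["timestamps_s"]), np.asarray(meta["plane_index"]),
        [tuple(i) for i in meta["stim_intervals_s"]], meta["pixel_rate_hz"],
        meta["stim_rep_rate_hz"], meta["scan_model"],
    )


def save_mask_tiff(mask: np.ndarray, path) -> None:
    """1-bit style artifact mask export (stored as uint8 0/1 pages)."""
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8), photometric="minisblack")


def load_mask_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


# ---------------------------------------------------------------------------
# traces and trials
# ---------------------------------------------------------------------------

def save_traces_csv(traces: TraceSet, path) -> None:
    """Long format: roi, t, dff, deconvolved."""
    n, t = traces.dff.shape
    df = pd.DataFrame({
        "roi": np.repeat(np.arange(n), t),
        "t": np.tile(traces.timestamps, n),
        "dff": traces.dff.ravel(),
        "deconvolved": (traces.deconvolved.ravel() if traces.deconvolved is not None
                        else np.full(n * t, np.nan)),
    })
    df.to_csv(path, index=False)


def save_traces_h5(traces: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traces.positions)
        f.create_dataset("dff", data=traces.dff)
        f.create_dataset("timestamps", data=traces.timestamps)
        if traces.deconvolved is not None:
            f.create_dataset("deconvolved", data=traces.deconvolved)
        f.attrs["trials"] = json.dumps([
            {
                "pattern_id": tr.pattern_id,
                "trial_index": tr.trial_index,
                "stim_start": tr.stim_start,
                "stim_end": tr.stim_end,
                "targeted": list(tr.targeted),
            }
            for tr in traces.trials
        ])


def load_traces_h5(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        trials = [
            Trial(t["pattern_id"], t["trial_index"], t["stim_start"], t["stim_end"],
                  tuple(t["targeted"]))
            for t in json.loads(f.attrs["trials"])
        ]
        return TraceSet(
            positions=f["positions"][...],
            dff=f["dff"][...],
            timestamps=f["timestamps"][...],
            deconvolved=f["deconvolved"][...] if "deconvolved" in f else None,
            trials=trials,
        )


def save_trials_json(trials: list[Trial], path) -> None:
    Path(path).write_text(json.dumps([
        {
            "pattern_id": tr.pattern_id, "trial_index": tr.trial_index,
            "stim_start": tr.stim_start, "stim_end": tr.stim_end,
            "targeted": list(tr.targeted),
        }
        for tr in trials
    ], indent=2))


def load_trials_json(path) -> list[Trial]:
    return [
        Trial(t["pattern_id"], t["trial_index"], t["stim_start"], t["stim_end"],
              tuple(t["targeted"]))
        for t in json.loads(Path(path).read_text())
    ]
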