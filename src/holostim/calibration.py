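"""SLM-to-imaging coordinate registration and diffraction-efficiency fitting.

The photostimulation (SLM) coordinate frame and the imaging frame are
related, at each defocus depth, by a 2D affine transform extracted from
burned-spot grids.  Calibrations are acquired every 25 um of depth and
linearly interpolated in between.  The SLM's steering efficiency drops with
deflection angle; a separable linear-in-distance model eta(x, y, z) is
fitted to measured per-target powers and consumed by
:func:`holostim.optics.compensate_efficiency`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("holostim")

#: default spacing of the calibration planes (um)
CALIBRATION_DEPTH_STEP_UM = 25.0


@dataclass
class Affine:
    """2D affine map y = A @ x + b."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "Affine":
        inv = np.linalg.inv(self.matrix)
        return Affine(inv, -inv @ self.offset)

    @staticmethod
    def identity() -> "Affine":
        return Affine(np.eye(2), np.zeros(2))


def fit_affine(slm_points: np.ndarray, image_points: np.ndarray) -> Affine:
    """Least-squares 2D affine from point correspondences.

    Requires at least 3 non-collinear pairs (the standard fixture is a 7x7
    grid over 240 x 240 um).  Returns the transform with its RMS residual.
    """
    src = np.atleast_2d(np.asarray(slm_points, dtype=float))
    dst = np.atleast_2d(np.asarray(image_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("point sets must be matching (N, 2) arrays")
    if len(src) < 3:
        raise ValueError("need >= 3 point pairs to fit an affine")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("points are collinear; affine is underdetermined")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = dst - design @ coef
    # per-coordinate RMS, comparable to the localization noise sigma
    rms = float(np.sqrt(np.mean(resid**2)))
    return Affine(matrix, offset, rms)


@dataclass
class AffineCalibration:
    """Per-depth affine transforms with linear interpolation in z."""

    depths: np.ndarray
    transforms: list[Affine] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.depths) != len(self.transforms):
            raise ValueError("one transform per depth required")
        if len(self.depths) == 0:
            raise ValueError("empty calibration")
        if len(self.depths) > 1 and not np.all(np.diff(self.depths) > 0):
            raise ValueError("depths must be strictly increasing")

    def to_json(self, path) -> None:
        import datetime

        payload = {
            "depths_um": self.depths.tolist(),
            "transforms": [
                {
                    "matrix": t.matrix.tolist(),
                    "offset": t.offset.tolist(),
                    "residual_rms": t.residual_rms,
                }
                for t in self.transforms
            ],
            "date": datetime.date.today().isoformat(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def from_json(path) -> "AffineCalibration":
        with open(path) as fh:
            payload = json.load(fh)
        transforms = [
            Affine(np.array(t["matrix"]), np.array(t["offset"]), t.get("residual_rms", 0.0))
            for t in payload["transforms"]
        ]
        return AffineCalibration(np.array(payload["depths_um"]), transforms)


def interp_affine(cal: AffineCalibration, z: float) -> Affine:
    """Affine at depth z by elementwise linear interpolation between knots.

    Exact (bit-identical) at a calibration depth.  Beyond the outermost
    knots the nearest transform is returned with a warning; requests more
    than one calibration step (25 um) outside the calibrated band are
    rejected.
    """
    depths = cal.depths
    lo, hi = depths[0], depths[-1]
    if z < lo - CALIBRATION_DEPTH_STEP_UM or z > hi + CALIBRATION_DEPTH_STEP_UM:
        raise ValueError(
            f"z = {z:g} um is more than {CALIBRATION_DEPTH_STEP_UM:g} um outside "
            f"the calibrated band [{lo:g}, {hi:g}]"
        )
    if z <= lo or z >= hi:
        if z < lo or z > hi:
            warnings.warn(
                f"z = {z:g} um is outside the calibrated band [{lo:g}, {hi:g}]; "
                "clamping to the nearest calibration plane",
                stacklevel=2,
            )
        idx = 0 if z <= lo else len(depths) - 1
        t = cal.transforms[idx]
        return Affine(t.matrix.copy(), t.offset.copy(), t.residual_rms)
    j = int(np.searchsorted(depths, z, side="right"))
    i = j - 1
    if depths[i] == z:
        t = cal.transforms[i]
        return Affine(t.matrix.copy(), t.offset.copy(), t.residual_rms)
    w = (z - depths[i]) / (depths[j] - depths[i])
    a, b = cal.transforms[i], cal.transforms[j]
    return Affine(
        (1 - w) * a.matrix + w * b.matrix,
        (1 - w) * a.offset + w * b.offset,
        float((1 - w) * a.residual_rms + w * b.residual_rms),
    )


# ---------------------------------------------------------------------------
# diffraction-efficiency model
# ---------------------------------------------------------------------------

@dataclass
class EfficiencyModel:
    """Steering efficiency eta(x, y, z) = c0 + c1|x| + c2|y| + c3|z|.

    Normalized so eta(0, 0, 0) = 1 and clamped to (0, 1] on evaluation;
    the raw fitted coefficients (before normalization) are kept in
    ``coefficients``.  An optional bilinear variant adds |x||y|, |x||z|,
    |y||z| cross terms.
    """

    coefficients: np.ndarray
    model: str = "separable"
    residual_rms: float = 0.0
    floor: float = 1e-6

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients[0] <= 0:
            raise ValueError("efficiency at the origin must be positive")

    def _design(self, x, y, z) -> np.ndarray:
        ax, ay, az = np.broadcast_arrays(
            np.abs(np.asarray(x, dtype=float)),
            np.abs(np.asarray(y, dtype=float)),
            np.abs(np.asarray(z, dtype=float)),
        )
        cols = [np.ones_like(ax), ax, ay, az]
        if self.model == "bilinear":
            cols += [ax * ay, ax * az, ay * az]
        return np.column_stack([np.ravel(c) for c in cols])

    def efficiency(self, x, y, z) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        shape = x.shape
        raw = self._design(x, y, z) @ self.coefficients / self.coefficients[0]
        return np.clip(raw, self.floor, 1.0).reshape(shape)


def fit_efficiency(
    positions: np.ndarray,
    measured_powers: np.ndarray,
    model: str = "separable",
) -> EfficiencyModel:
    """Fit the linear-in-distance efficiency model to measured powers.

    ``positions`` is (N, 3) in um; ``measured_powers`` the delivered power
    at each position for equal requested weight.  Requires >= 5 points
    spanning the range; the model is normalized to 1 at the origin.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    p = np.asarray(measured_powers, dtype=float).ravel()
    if pos.shape[0] != p.size or pos.shape[1] != 3:
        raise ValueError("positions must be (N, 3) with one power per point")
    if len(pos) < 5:
        raise ValueError("need >= 5 measurement points")
    probe = EfficiencyModel(np.array([1.0]+[0.0]*(6 if model == "bilinear" else 3)), model)
    design = probe._design(pos[:, 0], pos[:, 1], pos[:, 2])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("degenerate design matrix; spread measurement points in x, y, z")
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    resid = p - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    if coef[0] <= 0:
        raise ValueError("fitted efficiency at the origin is non-positive")
    return EfficiencyModel(coef, model, rms)
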