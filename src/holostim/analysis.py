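"""Photostimulation response statistics from calcium traces.

Covers the downstream analysis chain: stimulation-evoked dF/F changes,
binary activity-event detection from the deconvolved trace and the dF/F
derivative, responder/non-responder classification over trials, ensemble
response rates, distance-resolved nonspecific activation of non-targeted
cells, two-orientation selectivity, and per-ROI condition comparisons.

A minimal AR(1)-inverse deconvolution stand-in is provided for pipelines
that do not carry an upstream (CNMF-style) deconvolved signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger("holostim")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One photostimulation trial: a pattern applied over a time window."""

    pattern_id: int
    trial_index: int
    stim_start: float
    stim_end: float
    targeted: tuple[int, ...]  # ROI indices carrying a beamlet

    def __post_init__(self) -> None:
        if self.stim_end <= self.stim_start:
            raise ValueError("trial stimulation window must have positive length")


@dataclass
class TraceSet:
    """Aligned per-ROI traces with trial structure.

    ``dff`` and ``deconvolved`` are (n_roi, n_t) arrays on the shared
    ``timestamps``; ``positions`` is (n_roi, 3) in um.
    """

    positions: np.ndarray
    dff: np.ndarray
    timestamps: np.ndarray
    deconvolved: np.ndarray | None = None
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n, t = self.dff.shape
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_roi, 3)")
        if len(self.timestamps) != t:
            raise ValueError("timestamps must match the trace length")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.deconvolved is not None:
            self.deconvolved = np.atleast_2d(np.asarray(self.deconvolved, dtype=float))
            if self.deconvolved.shape != self.dff.shape:
                raise ValueError("deconvolved must match dff shape")
            if np.any(self.deconvolved < 0):
                raise ValueError("deconvolved signal must be nonnegative")

    @property
    def n_roi(self) -> int:
        return self.dff.shape[0]

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


# ---------------------------------------------------------------------------
# evoked response
# ---------------------------------------------------------------------------

def stim_response(
    trace: np.ndarray,
    timestamps: np.ndarray,
    stim_start: float,
    stim_end: float,
    baseline_s: float = 1.0,
    window: str = "during",
    post_window_s: float = 1.0,
) -> float:
    """Evoked fractional fluorescence change for one ROI and trial.

    (mean F during the response window - baseline mean) / baseline mean,
    with the baseline taken over ``baseline_s`` seconds (0.5-2 s is typical)
    ending at stimulation onset.  ``window="during"`` averages over the
    stimulation period itself; ``window="post"`` uses the first
    ``post_window_s`` seconds after stimulation end — the artifact-free
    fallback.  ``trace`` is raw fluorescence (or any positively offset
    signal); a non-positive baseline is an error.
    """
    trace = np.asarray(trace, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if not 0.0 < baseline_s:
        raise ValueError("baseline window must be positive")
    b0 = stim_start - baseline_s
    if b0 < timestamps[0] - 1e-9:
        raise ValueError("baseline window starts before the recording")
    base_sel = (timestamps >= b0) & (timestamps < stim_start)
    if window == "during":
        resp_sel = (timestamps >= stim_start) & (timestamps <= stim_end)
    elif window == "post":
        resp_sel = (timestamps > stim_end) & (timestamps <= stim_end + post_window_s)
    else:
        raise ValueError(f"unknown response window {window!r}")
    if not base_sel.any() or not resp_sel.any():
        raise ValueError("baseline or response window contains no samples")
    base = float(trace[base_sel].mean())
    if base <= 0:
        raise ValueError("non-positive baseline mean; pass raw fluorescence, not dF/F")
    return (float(trace[resp_sel].mean()) - base) / base


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_events(traces: TraceSet, k_sd: float = 2.0) -> np.ndarray:
    """Binary activity events per ROI and time point.

    An event is recorded where the deconvolved signal exceeds its mean by
    ``k_sd`` standard deviations AND the temporal first derivative of dF/F
    exceeds the derivative's own mean by ``k_sd`` of its SD (both statistics
    over the full trace).  Thresholds are SD-relative, so events are
    invariant under positive rescaling of the raw trace.
    """
    if traces.deconvolved is None:
        raise ValueError("deconvolved signal required; see deconvolve_stub")
    if traces.dff.shape[1] < 100:
        warnings.warn("fewer than 100 samples; event thresholds may be unstable",
                      stacklevel=2)
    dec = traces.deconvolved
    deriv = np.diff(traces.dff, axis=1, prepend=traces.dff[:, :1])
    sd_dec = dec.std(axis=1, keepdims=True)
    sd_der = deriv.std(axis=1, keepdims=True)
    flat = np.flatnonzero((sd_dec.ravel() == 0) | (sd_der.ravel() == 0))
    if flat.size:
        warnings.warn(f"{flat.size} ROI(s) have constant traces; no events detected",
                      stacklevel=2)
    thr_dec = dec.mean(axis=1, keepdims=True) + k_sd * sd_dec
    thr_der = deriv.mean(axis=1, keepdims=True) + k_sd * sd_der
    return (dec > thr_dec) & (deriv > thr_der)


def trial_event_matrix(
    events: np.ndarray,
    timestamps: np.ndarray,
    trials: list[Trial],
    pad_s: float = 0.0,
) -> np.ndarray:
    """(n_trials, n_roi) flags: any event inside each trial's stimulation
    window (optionally extended by ``pad_s`` seconds to catch indicator
    rise-time lag)."""
    events = np.atleast_2d(events)
    out = np.zeros((len(trials), events.shape[0]), dtype=bool)
    for i, tr in enumerate(trials):
        sel = (timestamps >= tr.stim_start) & (timestamps <= tr.stim_end + pad_s)
        out[i] = events[:, sel].any(axis=1)
    return out


def classify_nonresponder(
    events: np.ndarray,
    timestamps: np.ndarray,
    trials: list[Trial],
    pad_s: float = 0.0,
) -> np.ndarray:
    """Per-ROI flag: True if no event occurs during *any* trial's window.

    Cells silent across every photostimulation trial are attributed to poor
    opsin expression and excluded from response-rate statistics.
    """
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to classify non-responders")
    return ~trial_event_matrix(events, timestamps, trials, pad_s).any(axis=0)


def ensemble_response_rate(responded: np.ndarray) -> float:
    """Percentage of the targeted ensemble responding, averaged over trials.

    ``responded`` is (n_trials, n_targeted) boolean.
    """
    responded = np.atleast_2d(np.asarray(responded, dtype=bool))
    if responded.shape[1] == 0:
        raise ValueError("targeted ensemble is empty")
    return float(responded.mean(axis=1).mean() * 100.0)


# ---------------------------------------------------------------------------
# nonspecific activation vs distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceCurve:
    """Nonspecific activation vs 3D distance to the nearest targeted cell.

    ``values`` are per-bin mean responses normalized to the mean targeted
    response (empty bins are NaN); ``half_distance_um`` is where the curve,
    anchored at 1.0 for the targeted cells (d = 0), first falls through 0.5.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    half_distance_um: float


def nonspecific_vs_distance(
    positions: np.ndarray,
    targeted: np.ndarray,
    responses: np.ndarray,
    bin_width_um: float = 10.0,
    max_distance_um: float | None = None,
) -> DistanceCurve:
    """Bin non-targeted responses by nearest-target distance.

    ``responses`` holds one (trial-averaged) response per ROI; they are
    normalized by the mean response of the targeted cells, which must be
    positive.  The half-response distance is found by linear interpolation
    of the curve anchored at (0, 1).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    responses = np.asarray(responses, dtype=float)
    targeted = np.asarray(targeted, dtype=int)
    others = np.setdiff1d(np.arange(len(positions)), targeted)
    if len(others) == 0:
        raise ValueError("need at least one non-targeted ROI")
    tmean = responses[targeted].mean()
    if tmean <= 0:
        raise ValueError("mean targeted response must be positive for normalization")
    d = np.min(
        np.linalg.norm(positions[others][:, None, :] - positions[targeted][None, :, :], axis=2),
        axis=1,
    )
    norm = responses[others] / tmean
    if max_distance_um is None:
        max_distance_um = float(d.max()) + bin_width_um
    edges = np.arange(0.0, max_distance_um + bin_width_um, bin_width_um)
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    which = np.digitize(d, edges) - 1
    for b in range(len(centers)):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            values[b] = float(norm[sel].mean())

    # half-response distance: curve through (0, 1) and the populated bins
    xs = np.concatenate([[0.0], centers[counts > 0]])
    ys = np.concatenate([[1.0], values[counts > 0]])
    half = np.nan
    for i in range(1, len(xs)):
        if ys[i] <= 0.5 <= ys[i - 1]:
            t = (ys[i - 1] - 0.5) / (ys[i - 1] - ys[i])
            half = float(xs[i - 1] + t * (xs[i] - xs[i - 1]))
            break
    return DistanceCurve(centers, values, counts, half)


# ---------------------------------------------------------------------------
# orientation selectivity and condition comparison
# ---------------------------------------------------------------------------

def orientation_selectivity(dff_90, dff_0):
    """Two-orientation selectivity index and preferred orientation.

    index = |(dF/F|90 - dF/F|0) / (dF/F|90 + dF/F|0)|; preference is 90 for
    a positive numerator, 0 for negative.  A zero denominator yields NaN
    index and preference (flagged undefined).  Accepts scalars or arrays.
    """
    a = np.asarray(dff_90, dtype=float)
    b = np.asarray(dff_0, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(denom != 0, np.abs((a - b) / np.where(denom == 0, 1, denom)), np.nan)
    pref = np.where(a > b, 90.0, np.where(a < b, 0.0, np.nan))
    pref = np.where(denom == 0, np.nan, pref)
    if np.isscalar(dff_90) and np.isscalar(dff_0):
        return float(idx), (float(pref) if not np.isnan(pref) else np.nan)
    return idx, pref


@dataclass
class ConditionComparison:
    p_values: np.ndarray
    significant: np.ndarray
    undefined: np.ndarray


def compare_conditions(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    alpha: float = 0.05,
) -> ConditionComparison:
    """Per-ROI two-sample t-test between two trial ensembles.

    ``trials_a``/``trials_b`` are (n_roi, n_trials_*) response matrices.
    ROIs with zero variance in both conditions are flagged undefined (NaN p).
    """
    a = np.atleast_2d(np.asarray(trials_a, dtype=float))
    b = np.atleast_2d(np.asarray(trials_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("condition matrices must share the ROI dimension")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 trials per condition")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    undefined = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[undefined] = np.nan
    sig = np.where(np.isnan(p), False, p < alpha)
    return ConditionComparison(p, sig, undefined)


# ---------------------------------------------------------------------------
# deconvolution stand-in
# ---------------------------------------------------------------------------

def deconvolve_stub(dff: np.ndarray, dt: float, decay_tau: float = 1.5) -> np.ndarray:
    """Nonnegative AR(1)-inverse filter: max(0, x[t] - exp(-dt/tau)*x[t-1]).

    A stand-in for an upstream (CNMF-style) deconvolved output: a transient
    decaying with the matching tau collapses to a single positive sample at
    onset.  Replaceable by any proper deconvolution; it exists so the event
    detector always has a nonnegative event-probability series to threshold.
    """
    if decay_tau <= 0 or dt <= 0:
        raise ValueError("dt and decay_tau must be positive")
    x = np.atleast_2d(np.asarray(dff, dtype=float))
    g = np.exp(-dt / decay_tau)
    out = np.maximum(0.0, x - g * np.concatenate([x[:, :1], x[:, :-1]], axis=1))
    out[:, 0] = np.maximum(0.0, x[:, 0])
    return out if np.asarray(dff).ndim > 1 else out[0]


# ---------------------------------------------------------------------------
# ROI extraction helper
# ---------------------------------------------------------------------------

def roi_fluorescence(
    frames: np.ndarray,
    plane_index: np.ndarray,
    timestamps: np.ndarray,
    roi_centers_px: np.ndarray,
    roi_planes: np.ndarray,
    radius_px: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean fluorescence over a disk footprint per ROI, on its plane's frames.

    Returns (F, t) where F is (n_roi, n_plane_frames) and t the shared
    per-plane timestamp grid (all planes must have equal frame counts).  A
    simple segmentation-free extractor for synthetic data; real pipelines
    substitute CNMF traces upstream.
    """
    roi_centers_px = np.atleast_2d(roi_centers_px)
    roi_planes = np.asarray(roi_planes, dtype=int)
    h, w = frames.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    planes = np.unique(roi_planes)
    frames_per_plane = {p: np.flatnonzero(plane_index == p) for p in planes}
    counts = {p: len(v) for p, v in frames_per_plane.items()}
    if len(set(counts.values())) != 1:
        raise ValueError("planes have unequal frame counts; cannot align traces")
    n_t = next(iter(counts.values()))
    f_out = np.zeros((len(roi_centers_px), n_t))
    t_out = timestamps[frames_per_plane[planes[0]]]
    for i, ((cx, cy), p) in enumerate(zip(roi_centers_px, roi_planes)):
        foot = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
        if not foot.any():
            raise ValueError(f"ROI {i} footprint is empty")
        sel = frames_per_plane[int(p)]
        f_out[i] = frames[sel][:, foot].mean(axis=1)
    return f_out, t_out


def dff_from_fluorescence(f: np.ndarray, baseline_percentile: float = 20.0) -> np.ndarray:
    """dF/F with a per-ROI percentile baseline."""
    f = np.atleast_2d(np.asarray(f, dtype=float))
    f0 = np.percentile(f, baseline_percentile, axis=1, keepdims=True)
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline fluorescence")
    return (f - f0) / f0
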