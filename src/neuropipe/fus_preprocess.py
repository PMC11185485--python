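"""Voxel-wise preprocessing of power-Doppler time series.

The chain runs in a fixed order, mirroring how awake functional-ultrasound
recordings are conditioned before model fitting:

1. :func:`interpolate_to_rate` — resample every voxel onto a uniform 2 Hz grid;
2. :func:`delta_i_over_i` — convert to relative change against a pre-stimulus
   baseline mean (the ΔI/I unit used throughout);
3. :func:`highpass` — remove slow drifts with a fifth-order Butterworth
   high-pass at 0.056 Hz, applied forward-backward (zero phase);
4. :func:`remove_first_pc` — subtract the first spatiotemporal principal
   component of the whole session (global motion; awake recordings only);
5. :func:`scrub_motion` — flag frames above a per-voxel median + 4.44 x MAD
   threshold and replace them by linear interpolation.

Each stage stamps the series with its name; running stages out of order is
rejected so a pipeline cannot silently skip the unit conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .design import StimulusDesign

__all__ = [
    "FusSeries",
    "ScrubReport",
    "STAGES",
    "interpolate_to_rate",
    "delta_i_over_i",
    "highpass",
    "remove_first_pc",
    "scrub_motion",
]

#: Allowed processing stages, in pipeline order.
STAGES = ("raw", "interpolated", "dII", "filtered", "pc_removed", "scrubbed")


@dataclass
class FusSeries:
    """A voxels x frames power-Doppler matrix with frame timestamps.

    ``doppler`` holds raw intensity (a.u.) up to the ΔI/I stage and relative
    change (dimensionless) afterwards.  ``voxel_shape`` records the 3-D grid
    the flat voxel axis unravels to (C order); its product must equal the
    voxel count.
    """

    doppler: np.ndarray
    t: np.ndarray
    frame_rate_hz: float | None = None
    voxel_shape: tuple[int, ...] | None = None
    voxel_pitch_um: tuple[float, float, float] = (220.0, 280.0, 175.0)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.doppler = np.atleast_2d(np.asarray(self.doppler, dtype=float))
        self.t = np.asarray(self.t, dtype=float)
        if self.doppler.shape[1] != self.t.size:
            raise ValueError("doppler has a column per frame; t length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if self.voxel_shape is None:
            self.voxel_shape = (self.doppler.shape[0], 1, 1)
        if int(np.prod(self.voxel_shape)) != self.doppler.shape[0]:
            raise ValueError("product of voxel_shape must equal the voxel count")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def n_voxels(self) -> int:
        return self.doppler.shape[0]

    @property
    def n_frames(self) -> int:
        return self.doppler.shape[1]

    def _advance(self, doppler: np.ndarray, stage: str, **kw) -> "FusSeries":
        return replace(self, doppler=doppler, stage=stage, **kw)


def _require_stage(series: FusSeries, expected: str, op: str) -> None:
    if series.stage != expected:
        raise ValueError(
            f"{op} expects a series at stage {expected!r}, got {series.stage!r} "
            "(stages must be applied in pipeline order)"
        )


@dataclass
class ScrubReport:
    """Outcome of motion-artifact scrubbing."""

    threshold: np.ndarray                 # per-voxel threshold (a.u.)
    flagged: list[np.ndarray]             # per-voxel flagged frame indices
    flagged_fraction: float               # over all voxel-frame samples
    heavily_flagged_voxels: np.ndarray = field(default_factory=lambda: np.array([], int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel": np.arange(self.threshold.size),
                "threshold": self.threshold,
                "n_flagged": [f.size for f in self.flagged],
            }
        )


def interpolate_to_rate(series: FusSeries, target_hz: float = 2.0) -> FusSeries:
    """Resample every voxel onto a uniform grid at ``target_hz``.

    Linear interpolation over ``[t0, t_end]``; acquisition frame times may be
    jittered (the scanner produces a frame roughly every 500 ms, not exactly).
    """
    _require_stage(series, "raw", "interpolate_to_rate")
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to interpolate")
    t0, t_end = series.t[0], series.t[-1]
    n_out = int(np.floor((t_end - t0) * target_hz)) + 1
    t_new = t0 + np.arange(n_out) / target_hz
    out = np.empty((series.n_voxels, n_out))
    for v in range(series.n_voxels):
        out[v] = np.interp(t_new, series.t, series.doppler[v])
    return series._advance(out, "interpolated", t=t_new, frame_rate_hz=float(target_hz))


def _segment_bounds(
    onset_idx: np.ndarray, baseline_n_frames: int, n_frames: int
) -> list[tuple[int, int, int]]:
    """(segment start, segment end, event index) triples partitioning the run.

    Each event's normalisation segment starts where its baseline window starts
    (``onset - baseline_n_frames``) and runs until the next event's baseline
    window begins; the first segment is extended back to frame 0.
    """
    starts = [int(o) - baseline_n_frames for o in onset_idx]
    bounds = []
    for i, _ in enumerate(onset_idx):
        lo = 0 if i == 0 else starts[i]
        hi = n_frames if i == len(onset_idx) - 1 else starts[i + 1]
        bounds.append((lo, hi, i))
    return bounds


def delta_i_over_i(
    series: FusSeries, design: StimulusDesign, baseline_n_frames: int = 11
) -> FusSeries:
    """Convert to relative change ΔI/I against per-event baseline means.

    For each stimulus event the baseline is the mean of the
    ``baseline_n_frames`` frames immediately before its onset; the series is
    partitioned at event baselines and each segment is normalised as
    ``(x - b) / b`` with its own event's baseline ``b``.  Presets of 11 and
    70 baseline frames cover short- and long-ITI block designs.
    """
    _require_stage(series, "interpolated", "delta_i_over_i")
    if series.frame_rate_hz is None:
        raise ValueError("series must carry a frame rate")
    fr = series.frame_rate_hz
    onset_idx = np.round((np.asarray(design.onsets) - series.t[0]) * fr).astype(int)
    if np.any(onset_idx - baseline_n_frames < 0):
        raise ValueError(
            f"each event must be preceded by >= {baseline_n_frames} frames"
        )
    out = np.empty_like(series.doppler)
    for lo, hi, i in _segment_bounds(onset_idx, baseline_n_frames, series.n_frames):
        b = series.doppler[:, onset_idx[i] - baseline_n_frames : onset_idx[i]].mean(axis=1)
        bad = np.flatnonzero(b <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive baseline for voxel(s) {bad[:5].tolist()} at event {i}"
            )
        out[:, lo:hi] = (series.doppler[:, lo:hi] - b[:, None]) / b[:, None]
    return series._advance(out, "dII")


def highpass(
    series: FusSeries, cutoff_hz: float = 0.056, order: int = 5
) -> FusSeries:
    """Zero-phase Butterworth high-pass to remove slow drifts.

    Applied forward-backward per voxel so the slow hemodynamic response is not
    lagged; the effective magnitude order therefore doubles.
    """
    _require_stage(series, "dII", "highpass")
    fr = series.frame_rate_hz
    if fr is None or fr <= 2 * cutoff_hz:
        raise ValueError("frame rate must exceed twice the cutoff frequency")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fr, output="sos")
    padlen = 3 * (2 * order + 1)
    if series.n_frames <= padlen:
        raise ValueError(
            f"series too short to filter: {series.n_frames} frames <= padlen {padlen}"
        )
    out = signal.sosfiltfilt(sos, series.doppler, axis=1)
    return series._advance(out, "filtered")


def remove_first_pc(series: FusSeries) -> FusSeries:
    """Subtract the first spatiotemporal principal component of the session.

    The voxels x frames matrix is decomposed by SVD and the rank-1 term
    ``s1 * u1 v1^T`` removed.  This targets global (motion-driven) intensity
    fluctuations that dominate awake recordings; anesthetized sessions can
    skip the stage (see the pipeline runner's ``skip_pc`` flag).
    """
    _require_stage(series, "filtered", "remove_first_pc")
    if series.n_voxels < 2 or series.n_frames < 2:
        raise ValueError("need at least a 2 x 2 matrix for PC removal")
    x = series.doppler
    norm = np.linalg.norm(x)
    if norm == 0:
        warnings.warn("all-zero series: first-PC removal is a no-op")
        return series._advance(x.copy(), "pc_removed")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    out = x - s[0] * np.outer(u[:, 0], vt[0])
    return series._advance(out, "pc_removed")


def _mad(x: np.ndarray, axis: int = -1) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


def _interpolate_flagged(trace: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Replace flagged samples by linear interpolation across unflagged ones.

    Edge runs with no two-sided neighbour take the nearest unflagged value.
    """
    out = trace.copy()
    good = np.ones(trace.size, dtype=bool)
    good[flagged] = False
    if not good.any():
        return out
    idx = np.arange(trace.size)
    out[~good] = np.interp(idx[~good], idx[good], trace[good])
    return out


def scrub_motion(series: FusSeries, k: float = 4.44) -> tuple[FusSeries, ScrubReport]:
    """Flag and repair motion-artifact frames with a robust per-voxel rule.

    A frame is flagged when its value exceeds ``median + k x MAD`` of that
    voxel's trace (MAD = median absolute deviation, unscaled; k = 4.44 is
    roughly a 3-sigma rule for Gaussian data).  Flagged frames are replaced by
    linear interpolation across neighbouring unflagged frames.
    """
    _require_stage(series, "pc_removed", "scrub_motion")
    if k <= 0 and np.isfinite(k):
        raise ValueError("scrub multiplier k must be positive")
    x = series.doppler
    med = np.median(x, axis=1)
    mad = _mad(x, axis=1)
    if np.isinf(k):
        thresh = np.full(series.n_voxels, np.inf)
    else:
        thresh = med + k * mad
    out = np.empty_like(x)
    flagged_lists: list[np.ndarray] = []
    heavy = []
    for v in range(series.n_voxels):
        flagged = np.flatnonzero(x[v] > thresh[v]) if np.isfinite(thresh[v]) else np.array([], int)
        if flagged.size > 0.5 * series.n_frames:
            heavy.append(v)
        flagged_lists.append(flagged)
        out[v] = _interpolate_flagged(x[v], flagged)
    if heavy:
        warnings.warn(
            f"{len(heavy)} voxel(s) had > 50% of frames flagged; values were "
            "still interpolated but are unreliable"
        )
    frac = sum(f.size for f in flagged_lists) / x.size
    report = ScrubReport(
        threshold=thresh,
        flagged=flagged_lists,
        flagged_fraction=float(frac),
        heavily_flagged_voxels=np.array(heavy, int),
    )
    return series._advance(out, "scrubbed"), report
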