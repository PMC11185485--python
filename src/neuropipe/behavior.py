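"""Open-field locomotion metrics and head-fixed behavioural readouts.

Open-field positions are downsampled (factor 3), smoothed over a 0.5-s
window, and summarised by distance, speed, and path *tortuosity*: the ratio
of the distance actually travelled within a 1.2-s sliding window to the
straight chord between the window's endpoints (1 = perfectly straight).  The
animal-level statistic is the median tortuosity over samples where the mouse
is running, with the running threshold defined as the average 75th-percentile
speed of control animals.

Head-fixed readouts are a paw-keypoint locomotion trace (mean per-paw
frame-to-frame displacement, smoothed 0.5 s), a motion-energy trace (mean
absolute inter-frame pixel difference within an ROI), per-trial z-scoring
against the 40 s before stimulus onset, and a locomotion / no-locomotion
trial split at a mean-z threshold of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import StimulusDesign
from .fus_activation import moving_average

__all__ = [
    "Trajectory",
    "MotionEnergyTrace",
    "preprocess_trajectory",
    "running_threshold",
    "tortuosity",
    "keypoint_locomotion",
    "motion_energy",
    "zscore_trials",
    "split_trials_by_locomotion",
]


@dataclass
class Trajectory:
    """Timestamped 2-D positions (cm) with derived speed."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate_hz: float
    speed: np.ndarray | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal lengths")
        if self.speed is not None and np.any(np.asarray(self.speed) < 0):
            raise ValueError("speed must be nonnegative")

    @property
    def n(self) -> int:
        return self.t.size

    def total_distance(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


def preprocess_trajectory(
    raw: Trajectory, downsample: int = 3, smooth_s: float = 0.5
) -> Trajectory:
    """Downsample, smooth positions, and derive per-sample speed.

    Every ``downsample``-th sample is kept, positions are moving-averaged over
    ``smooth_s``, and speed is computed from the smoothed positions as
    displacement times the output frame rate (first sample repeats the
    second, so speed stays aligned with positions).
    """
    if raw.state != "raw":
        raise ValueError("preprocess_trajectory expects a raw trajectory")
    fs_out = raw.frame_rate_hz / downsample
    x = raw.x[::downsample]
    y = raw.y[::downsample]
    t = raw.t[::downsample]
    win = max(1, int(round(smooth_s * fs_out)))
    if x.size < win:
        raise ValueError("trajectory shorter than the smoothing window")
    xs = moving_average(x, win)
    ys = moving_average(y, win)
    disp = np.hypot(np.diff(xs), np.diff(ys))
    speed = np.concatenate([[disp[0] if disp.size else 0.0], disp]) * fs_out
    return Trajectory(t=t, x=xs, y=ys, frame_rate_hz=fs_out,
                      speed=speed, state="smoothed")


def running_threshold(control_speed_traces: list[np.ndarray]) -> float:
    """Average of per-animal 75th-percentile speeds (control animals).

    Percentiles use linear interpolation between order statistics.
    """
    if not control_speed_traces:
        raise ValueError("need at least one control speed trace")
    return float(np.mean([np.percentile(np.asarray(s, float), 75)
                          for s in control_speed_traces]))


def tortuosity(
    traj: Trajectory, window_s: float = 1.2, run_threshold: float = 0.0
) -> tuple[np.ndarray, float]:
    """Sliding-window path/chord ratio and its running-sample median.

    The window is centered on each sample (edge windows are dropped — NaN);
    path length is the summed step length within the window and the chord is
    the straight-line distance between its endpoints.  Windows that return to
    their start (zero chord) are undefined and excluded.  The summary value
    is the median over samples whose speed exceeds ``run_threshold``.
    """
    if traj.state != "smoothed":
        raise ValueError("tortuosity expects a smoothed trajectory")
    n_side = int(round(window_s * traj.frame_rate_hz / 2))
    if 2 * n_side < 2:
        raise ValueError("window must span at least 3 samples")
    n = traj.n
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    csum = np.concatenate([[0.0], np.cumsum(steps)])
    tort = np.full(n, np.nan)
    for i in range(n_side, n - n_side):
        a, b = i - n_side, i + n_side
        path = csum[b] - csum[a]
        chord = np.hypot(traj.x[b] - traj.x[a], traj.y[b] - traj.y[a])
        if chord > 0:
            tort[i] = path / chord
    speed = traj.speed if traj.speed is not None else np.zeros(n)
    sel = (~np.isnan(tort)) & (speed > run_threshold)
    med = float(np.median(tort[sel])) if sel.any() else np.nan
    return tort, med


def keypoint_locomotion(
    paw_xy: list[np.ndarray],
    frame_rate_hz: float = 30.0,
    smooth_s: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Locomotion trace from paw keypoints.

    Each paw's per-frame Euclidean displacement relative to the previous frame
    is averaged across paws and smoothed with a 0.5-s (15 frames at 30 Hz)
    sliding window.  NaN keypoints (low tracking confidence) are linearly
    interpolated first; returns the trace and the gap fraction interpolated.
    """
    if not paw_xy:
        raise ValueError("need at least one paw")
    n = paw_xy[0].shape[0]
    disps = []
    n_gap = 0
    for xy in paw_xy:
        xy = np.asarray(xy, float)
        if xy.shape != (n, 2):
            raise ValueError("paw series must share length and be (n, 2)")
        filled = xy.copy()
        for c in range(2):
            bad = np.isnan(filled[:, c])
            n_gap += int(bad.sum())
            if bad.any():
                if bad.all():
                    raise ValueError("a paw coordinate is entirely missing")
                idx = np.arange(n)
                filled[bad, c] = np.interp(idx[bad], idx[~bad], filled[~bad, c])
        d = np.hypot(np.diff(filled[:, 0]), np.diff(filled[:, 1]))
        disps.append(np.concatenate([[0.0], d]))
    trace = np.mean(disps, axis=0)
    win = max(1, int(round(smooth_s * frame_rate_hz)))
    return moving_average(trace, win), n_gap / (2 * n * len(paw_xy))


@dataclass
class MotionEnergyTrace:
    """Per-frame motion energy (a.u.) for one named ROI."""

    values: np.ndarray
    roi_name: str = "roi"
    frame_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("motion energy must be nonnegative")


def motion_energy(
    frames: np.ndarray, roi: tuple[slice, slice], roi_name: str = "roi",
    frame_rate_hz: float = 20.0,
) -> MotionEnergyTrace:
    """Mean absolute inter-frame pixel difference within an ROI (frame 0 = 0)."""
    frames = np.asarray(frames, float)
    sub = frames[:, roi[0], roi[1]]
    if sub.shape[1] == 0 or sub.shape[2] == 0:
        raise ValueError("empty ROI")
    vals = np.zeros(frames.shape[0])
    vals[1:] = np.abs(np.diff(sub, axis=0)).mean(axis=(1, 2))
    return MotionEnergyTrace(values=vals, roi_name=roi_name,
                             frame_rate_hz=frame_rate_hz)


@dataclass
class TrialSegments:
    """Trial-aligned z-scored segments of one behavioural trace."""

    z: np.ndarray              # n_trials x n_samples (NaN-padded where short)
    t_rel: np.ndarray          # seconds relative to stimulus onset
    valid: np.ndarray          # per-trial flag (False: zero baseline SD)


def zscore_trials(
    trace: MotionEnergyTrace | np.ndarray,
    design: StimulusDesign,
    frame_rate_hz: float | None = None,
    baseline_s: float = 40.0,
    post_s: float | None = None,
) -> TrialSegments:
    """Z-score each trial against its own pre-onset baseline window.

    For every trial the mean and SD of the ``baseline_s`` seconds before
    onset define ``z = (x - mean) / sd`` over ``[-baseline_s, duration +
    post_s]``; trials with zero baseline SD are flagged invalid.  ``post_s``
    defaults to 10 s past stimulus offset (the window the locomotion split
    uses).
    """
    if isinstance(trace, MotionEnergyTrace):
        values = trace.values
        fr = trace.frame_rate_hz
    else:
        values = np.asarray(trace, float)
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz required for a bare array")
        fr = frame_rate_hz
    post_s = 10.0 if post_s is None else post_s
    nb = int(round(baseline_s * fr))
    segs, valids = [], []
    n_post = max(int(round((d + post_s) * fr)) for _, d, _ in design.events)
    for onset, dur, _ in design.events:
        i0 = int(round(onset * fr))
        if i0 - nb < 0:
            raise ValueError(
                f"trial at {onset} s lacks {baseline_s} s of pre-onset data"
            )
        base = values[i0 - nb : i0]
        seg = values[i0 - nb : min(i0 + n_post, values.size)].astype(float)
        if seg.size < nb + n_post:
            seg = np.concatenate([seg, np.full(nb + n_post - seg.size, np.nan)])
        sd = base.std()
        if sd == 0:
            valids.append(False)
            segs.append(np.full(nb + n_post, np.nan))
        else:
            valids.append(True)
            segs.append((seg - base.mean()) / sd)
    t_rel = (np.arange(nb + n_post) - nb) / fr
    return TrialSegments(z=np.vstack(segs), t_rel=t_rel,
                         valid=np.array(valids, bool))


def split_trials_by_locomotion(
    segments: TrialSegments,
    design: StimulusDesign,
    post_offset_s: float = 10.0,
    threshold: float = 2.0,
) -> list[str]:
    """Label each trial "locomotion" / "no locomotion" by mean z-score.

    The window runs from stimulus onset to ``post_offset_s`` after offset;
    mean z strictly above ``threshold`` means locomotion (a mean of exactly
    2 counts as "no locomotion").  Invalid trials get "invalid".
    """
    labels = []
    for i, (onset, dur, _) in enumerate(design.events):
        if not segments.valid[i]:
            labels.append("invalid")
            continue
        sel = (segments.t_rel >= 0) & (segments.t_rel < dur + post_offset_s)
        mean_z = np.nanmean(segments.z[i, sel])
        labels.append("locomotion" if mean_z > threshold else "no locomotion")
    return labels
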