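"""Spike-train analysis: rate estimation, trial averaging, response typing.

Spike times are binned at 1 ms and convolved with a unit-area Gaussian
kernel (SD 10 ms, truncated at +/-4 SD) to give a continuous firing-rate
estimate in Hz.  For trial-level summaries the rate is smoothed with a 70-ms
moving window, averaged across stimulus-aligned trials, and z-scored against
the 4.5 s before onset.  Response types follow fixed correlation rules on
the trial-averaged rate: r > 0.2 with the stimulus boxcar defines an ON
cell, r < -0.2 a deactivated cell, and r > 0.2 with a boxcar spanning
stimulus offset to 800 ms after it an OFF cell (precedence ON, deactivated,
OFF; all three r values are reported so alternatives can be re-derived).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StimulusDesign
from .fus_activation import moving_average
from .synth import SpikeTrain

__all__ = [
    "SpikeTrain",
    "RateTrace",
    "TrialAverage",
    "firing_rate",
    "trial_average_z",
    "classify_response",
]


@dataclass
class RateTrace:
    """Continuous firing-rate estimate on a 1-ms grid."""

    t: np.ndarray
    rate: np.ndarray               # Hz
    bin_ms: float = 1.0
    kernel_sd_ms: float = 10.0
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state == "raw" and np.any(self.rate < -1e-12):
            raise ValueError("raw rate must be nonnegative")


def firing_rate(
    spikes: SpikeTrain, bin_ms: float = 1.0, kernel_sd_ms: float = 10.0
) -> RateTrace:
    """Gaussian-kernel rate estimate from a spike train.

    Counts in ``bin_ms`` bins are convolved with a unit-area Gaussian
    truncated at +/-4 SD (renormalised after truncation), then scaled to Hz,
    so the trace integrates to the spike count for interior spikes.  An empty
    train gives an all-zero trace.
    """
    if spikes.span_s <= 0:
        raise ValueError("recording span must be positive")
    dt = bin_ms / 1000.0
    n = int(round(spikes.span_s / dt))
    counts, _ = np.histogram(spikes.times, bins=n, range=(0.0, spikes.span_s))
    sd_bins = kernel_sd_ms / bin_ms
    half = int(np.ceil(4 * sd_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
    k /= k.sum()
    rate = np.convolve(counts.astype(float), k, mode="same") / dt
    t = (np.arange(n) + 0.5) * dt
    return RateTrace(t=t, rate=rate, bin_ms=bin_ms, kernel_sd_ms=kernel_sd_ms)


@dataclass
class TrialAverage:
    """Stimulus-aligned trial-average of one unit's rate."""

    t_rel: np.ndarray              # s relative to onset
    mean_rate: np.ndarray          # Hz, trial-averaged (smoothed)
    z: np.ndarray | None           # z-scored to the pre-onset baseline
    valid: bool                    # False when the baseline SD is zero
    duration_s: float              # stimulus duration of the aligned trials


def trial_average_z(
    rate: RateTrace,
    design: StimulusDesign,
    smooth_ms: float = 70.0,
    baseline_s: float = 4.5,
    post_s: float | None = None,
) -> TrialAverage:
    """Smooth, align to stimulus onsets, average trials, z-score to baseline.

    The rate is moving-average smoothed over ``smooth_ms``, segments spanning
    ``[-baseline_s, duration + post_s]`` are averaged across trials, and the
    average is z-scored against the mean/SD of its own pre-onset window.
    ``post_s`` defaults to 1 s past offset (covering the 800-ms OFF window).
    A zero baseline SD flags the unit invalid (``z = None``).
    """
    durations = np.unique(design.durations)
    if durations.size != 1:
        raise ValueError("trial averaging requires equal stimulus durations")
    dur = float(durations[0])
    post_s = 1.0 if post_s is None else post_s
    dt = rate.bin_ms / 1000.0
    win = max(1, int(round(smooth_ms / rate.bin_ms)))
    smoothed = moving_average(rate.rate, win)
    nb = int(round(baseline_s / dt))
    npost = int(round((dur + post_s) / dt))
    segs = []
    for onset in design.onsets:
        i0 = int(round(onset / dt))
        if i0 - nb < 0 or i0 + npost > smoothed.size:
            raise ValueError(
                f"trial at {onset} s lacks {baseline_s} s baseline or "
                f"{dur + post_s} s post-onset coverage"
            )
        segs.append(smoothed[i0 - nb : i0 + npost])
    mean_rate = np.mean(segs, axis=0)
    t_rel = (np.arange(-nb, npost) + 0.5) * dt
    base = mean_rate[:nb]
    sd = base.std()
    if sd == 0:
        return TrialAverage(t_rel=t_rel, mean_rate=mean_rate, z=None,
                            valid=False, duration_s=dur)
    z = (mean_rate - base.mean()) / sd
    return TrialAverage(t_rel=t_rel, mean_rate=mean_rate, z=z, valid=True,
                        duration_s=dur)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    d = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / d) if d > 0 else np.nan


def classify_response(
    avg: TrialAverage,
    r_thresh: float = 0.2,
    off_window_ms: float = 800.0,
) -> tuple[str, dict[str, float]]:
    """Classify a trial-averaged unit as ON / deactivated / OFF / none.

    Correlates the trial-averaged rate (from baseline through the OFF
    window) with the stimulus boxcar and with an offset boxcar spanning
    ``[offset, offset + off_window_ms]``.  Rules are applied with precedence
    ON, deactivated, OFF; the returned dict carries ``r_stim`` and ``r_off``
    so alternative precedences can be re-derived.
    """
    t = avg.t_rel
    off_end = avg.duration_s + off_window_ms / 1000.0
    sel = t < off_end
    x = avg.mean_rate[sel]
    stim_box = ((t >= 0) & (t < avg.duration_s)).astype(float)[sel]
    off_box = ((t >= avg.duration_s) & (t < off_end)).astype(float)[sel]
    r_stim = _corr(x, stim_box)
    r_off = _corr(x, off_box)
    rs = {"r_stim": r_stim, "r_off": r_off}
    if np.isnan(r_stim):
        return "none", rs
    if r_stim > r_thresh:
        return "ON", rs
    if r_stim < -r_thresh:
        return "deactivated", rs
    if not np.isnan(r_off) and r_off > r_thresh:
        return "OFF", rs
    return "none", rs
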