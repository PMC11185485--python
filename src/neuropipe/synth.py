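"""Synthetic data with known ground truth for every pipeline modality.

Each generator emulates the acquisition its downstream stage expects —
block-design power-Doppler series with hemodynamic responses, drift, a
global motion component and spike artifacts; schematic face videos whose
ear/snout configuration deforms with an emotion state; correlated-random-walk
open-field trajectories; locomotion-coupled fluorescence traces; and
inhomogeneous Poisson spike trains with ON / deactivated / OFF phenotypes —
and returns the ground truth needed to score recovery.  All generators are
bit-reproducible under a fixed seed.

The face renderer is deliberately schematic (geometric primitives on a noisy
background): it exists to exercise the discriminative behaviour of the HOG
prototype pipeline, not to look like a mouse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as _ellipse, line_aa as _line_aa

from .design import StimulusDesign
from .fus_activation import make_hrf
from .fus_preprocess import FusSeries

__all__ = [
    "PROTOCOLS",
    "FusGroundTruth",
    "FaceGroundTruth",
    "SpikeTrain",
    "gen_stimulus_design",
    "gen_tastant_design",
    "gen_fus_series",
    "gen_face_sequence",
    "gen_trajectory",
    "gen_locomotion",
    "gen_cell_traces",
    "gen_spike_trains",
    "allocate_counts",
]

PROTOCOLS = ("visual_block", "opto_fus", "opto_ephys")

#: Cardinal drifting-grating directions (degrees); metadata only — the
#: synthetic signal model is direction-agnostic.
DIRECTIONS = ("0", "90", "180", "270")


def gen_stimulus_design(
    protocol: str,
    seed: int = 0,
    n_trials: int | None = None,
    strict_period: bool = False,
) -> StimulusDesign:
    """Standard block designs for the three stimulation protocols.

    - ``visual_block``: 12 gratings blocks of 12 s separated by 12 s of gray;
      4 cardinal directions, each repeated 3x in seeded random order.
    - ``opto_fus``: 90 s baseline, then 15 trials of 10 s stimulation.  The
      default inter-onset interval is 100 s (10 s on + 90 s off); pass
      ``strict_period=True`` for an exact 90 s period instead.
    - ``opto_ephys``: 9 s baseline, then 1 s stimulation trials every 10 s
      (or every 9 s with ``strict_period=True``).
    """
    rng = np.random.default_rng(seed)
    if protocol == "visual_block":
        n = 12 if n_trials is None else n_trials
        labels = np.repeat(DIRECTIONS, max(1, n // len(DIRECTIONS)))[:n]
        labels = rng.permutation(labels)
        events = tuple(
            (12.0 + 24.0 * i, 12.0, str(labels[i])) for i in range(n)
        )
        return StimulusDesign(events=events, run_length_s=24.0 * n)
    if protocol == "opto_fus":
        n = 15 if n_trials is None else n_trials
        period = 90.0 if strict_period else 100.0
        events = tuple((90.0 + period * i, 10.0, "opto") for i in range(n))
        return StimulusDesign(events=events, run_length_s=90.0 + period * n)
    if protocol == "opto_ephys":
        n = 15 if n_trials is None else n_trials
        period = 9.0 if strict_period else 10.0
        events = tuple((9.0 + period * i, 1.0, "opto") for i in range(n))
        return StimulusDesign(events=events, run_length_s=9.0 + period * n)
    raise ValueError(
        f"unknown protocol {protocol!r}; valid protocols are {PROTOCOLS}"
    )


def gen_tastant_design(
    condition: str = "quinine",
    n_trials: int = 5,
    trial_s: float = 2.0,
    isi_s: float = 120.0,
    baseline_s: float = 20.0,
) -> StimulusDesign:
    """Tastant-delivery design: ``n_trials`` trials of ``trial_s`` seconds
    separated by ``isi_s`` of quiet, after an initial baseline."""
    events = tuple(
        (baseline_s + (trial_s + isi_s) * i, trial_s, condition)
        for i in range(n_trials)
    )
    return StimulusDesign(
        events=events, run_length_s=baseline_s + (trial_s + isi_s) * n_trials
    )


# ---------------------------------------------------------------------------
# functional ultrasound

@dataclass
class FusGroundTruth:
    """What was injected into a synthetic power-Doppler series."""

    active_mask: np.ndarray        # bool per voxel
    true_beta: np.ndarray          # peak ΔI/I response amplitude per voxel
    artifact_frames: np.ndarray    # frame indices carrying motion spikes
    global_component: np.ndarray   # shared motion time series (a.u.)
    regressor: np.ndarray          # unit-peak HRF-convolved stimulus course

    def __post_init__(self) -> None:
        if self.active_mask.size != self.true_beta.size:
            raise ValueError("active_mask and true_beta must share voxel count")
        if np.any(self.true_beta[~self.active_mask] != 0):
            raise ValueError("true_beta must be zero for inactive voxels")


def hrf_regressor(design: StimulusDesign, t: np.ndarray, frame_rate_hz: float) -> np.ndarray:
    """Unit-peak HRF-convolved stimulus time course (the generator's signal
    model; the same kernel the activation module uses)."""
    hrf = make_hrf(frame_rate_hz)
    box = design.boxcar(t)
    reg = np.convolve(box, hrf.kernel)[: t.size]
    peak = reg.max()
    return reg / peak if peak > 0 else reg


def gen_fus_series(
    design: StimulusDesign,
    n_voxels: int = 500,
    frame_rate_hz: float = 2.0,
    frac_active: float = 0.1,
    beta: float = 0.03,
    noise_sd: float = 0.01,
    n_artifacts: int = 0,
    global_amp: float = 0.0,
    drift_amp: float = 0.0,
    active_mask: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[FusSeries, FusGroundTruth]:
    """Block-design power-Doppler series with known active voxels.

    Active voxels carry the stimulus design convolved with the activation
    module's HRF, scaled to a peak relative response of ``beta`` (ΔI/I
    units), on a positive per-voxel baseline.  All voxels share a slow drift
    (amplitude ``drift_amp`` over the run) and ``global_amp`` times a common
    smooth "motion" component; ``n_artifacts`` distinct frames receive
    additive spikes of at least 8x the per-voxel MAD of the relative signal,
    so the k = 4.44 scrubbing rule must flag them.

    Pass ``active_mask`` to pin the active-voxel set (e.g. shared across the
    sessions of one simulated animal); otherwise ``frac_active`` of the
    voxels are drawn at random.
    """
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not 0 <= frac_active <= 1:
        raise ValueError("frac_active must lie in [0, 1]")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(design.run_length_s * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz

    reg = hrf_regressor(design, t, frame_rate_hz)
    if active_mask is not None:
        active = np.asarray(active_mask, bool)
        if active.size != n_voxels:
            raise ValueError("active_mask length must equal n_voxels")
    else:
        n_active = int(round(frac_active * n_voxels))
        active = np.zeros(n_voxels, dtype=bool)
        active[rng.choice(n_voxels, size=n_active, replace=False)] = True
    true_beta = np.where(active, beta, 0.0)

    # shared smooth motion component: low-passed white noise, unit SD
    g = rng.standard_normal(n_frames)
    width = max(1, int(round(2 * frame_rate_hz)))
    kern = np.exp(-0.5 * ((np.arange(-3 * width, 3 * width + 1)) / width) ** 2)
    g = np.convolve(g, kern / kern.sum(), mode="same")
    sd = g.std()
    if sd > 0:
        g = g / sd

    drift = drift_amp * np.linspace(-0.5, 0.5, n_frames)
    rel = (
        true_beta[:, None] * reg[None, :]
        + global_amp * g[None, :]
        + drift[None, :]
        + noise_sd * rng.standard_normal((n_voxels, n_frames))
    )

    artifact_frames = np.array([], dtype=int)
    if n_artifacts > 0:
        if n_artifacts > n_frames - 4:
            raise ValueError("too many artifact frames for the run length")
        candidates = np.arange(2, n_frames - 2)
        artifact_frames = np.sort(
            rng.choice(candidates, size=n_artifacts, replace=False)
        )
        med = np.median(rel, axis=1, keepdims=True)
        mad = np.median(np.abs(rel - med), axis=1)
        amp = 10.0 * np.maximum(mad, 0.005)
        rel[:, artifact_frames] += amp[:, None]

    baseline = rng.uniform(80.0, 120.0, size=n_voxels)
    doppler = baseline[:, None] * (1.0 + rel)
    series = FusSeries(doppler=doppler, t=t, frame_rate_hz=frame_rate_hz,
                       stage="raw")
    truth = FusGroundTruth(
        active_mask=active,
        true_beta=true_beta,
        artifact_frames=artifact_frames,
        global_component=g,
        regressor=reg,
    )
    return series, truth


# ---------------------------------------------------------------------------
# face videography

@dataclass
class FaceGroundTruth:
    """Per-frame expression state of a synthetic face video."""

    labels: list[str]              # in {"neutral", "pleasure", "disgust"}
    intensity: np.ndarray          # in [0, 1]; 0 iff neutral

    def __post_init__(self) -> None:
        for lab, inten in zip(self.labels, self.intensity):
            if (inten == 0) != (lab == "neutral"):
                raise ValueError("intensity 0 must coincide with neutral label")


_TASTANT_TO_EXPRESSION = {"sucrose": "pleasure", "quinine": "disgust"}


def _render_face(size: tuple[int, int], expression: str, intensity: float,
                 jitter: np.ndarray) -> np.ndarray:
    """Draw a schematic face.  ``jitter`` holds 6 small per-frame offsets."""
    h, w = size
    img = np.zeros((h, w))
    s = min(h, w)
    # head
    cy, cx = 0.52 * h + jitter[0], 0.55 * w + jitter[1]
    rr, cc = _ellipse(cy, cx, 0.34 * h, 0.40 * w, shape=img.shape)
    img[rr, cc] = 0.45
    # ear: pleasure pushes it forward/down, disgust pulls it back/up
    ear_dx = (0.10 if expression == "pleasure" else -0.10 if expression == "disgust" else 0.0)
    ear_dy = (0.05 if expression == "pleasure" else -0.06 if expression == "disgust" else 0.0)
    ey = (0.18 + ear_dy * intensity) * h + jitter[2]
    ex = (0.70 + ear_dx * intensity) * w + jitter[3]
    rr, cc = _ellipse(ey, ex, 0.12 * h, 0.10 * w, shape=img.shape)
    img[rr, cc] = 0.75
    # snout at the left edge of the head: disgust bulges it, pleasure relaxes
    sn = 1.0 + (0.45 if expression == "disgust" else -0.30 if expression == "pleasure" else 0.0) * intensity
    sy = 0.60 * h + jitter[4]
    sx = 0.18 * w + jitter[5]
    rr, cc = _ellipse(sy, sx, 0.10 * h * sn, 0.09 * w * sn, shape=img.shape)
    img[rr, cc] = 0.85
    # whiskers: straight lines whose droop tracks the expression
    droop = (0.12 if expression == "disgust" else -0.10 if expression == "pleasure" else 0.0) * intensity
    for k, base_dy in enumerate((-0.05, 0.02, 0.09)):
        y0 = int(np.clip(sy + base_dy * h, 0, h - 1))
        x0 = int(np.clip(sx + 0.02 * w, 0, w - 1))
        y1 = int(np.clip(y0 + (base_dy + droop) * 0.8 * h, 0, h - 1))
        x1 = int(np.clip(x0 - 0.16 * w, 0, w - 1))
        rr, cc, val = _line_aa(y0, x0, y1, x1)
        img[rr, cc] = np.maximum(img[rr, cc], val)
    return img


def gen_face_sequence(
    design: StimulusDesign,
    frame_rate_hz: float = 20.0,
    image_size: tuple[int, int] = (96, 96),
    ramp_s: float = 0.25,
    noise_sd: float = 4.0,
    seed: int = 0,
) -> tuple[np.ndarray, FaceGroundTruth]:
    """Schematic face video following a tastant design.

    During "sucrose" / "quinine" events the ear, snout and whisker parameters
    deform continuously toward the pleasure / disgust configuration with an
    intensity that ramps up over ``ramp_s`` and holds at 1; outside events
    the face is jittered neutral.  Returns a uint8 frame stack and the
    per-frame ground-truth labels/intensities.
    """
    if image_size[0] < 64 or image_size[1] < 64:
        raise ValueError("image_size must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    n_frames = int(round(design.run_length_s * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    labels = ["neutral"] * n_frames
    intensity = np.zeros(n_frames)
    for onset, dur, cond in design.events:
        expr = _TASTANT_TO_EXPRESSION.get(cond)
        if expr is None:
            continue
        idx = np.flatnonzero((t >= onset) & (t < onset + dur))
        for j in idx:
            frac = (t[j] - onset + 1.0 / frame_rate_hz) / max(ramp_s, 1e-9)
            intensity[j] = min(1.0, frac)
            labels[j] = expr
    stack = np.empty((n_frames, *image_size), dtype=np.uint8)
    s = min(image_size)
    for i in range(n_frames):
        jitter = rng.normal(0.0, 0.004 * s, size=6)
        img = _render_face(image_size, labels[i] if labels[i] != "neutral" else "neutral",
                           intensity[i], jitter)
        img = img * 200.0 + rng.normal(0.0, noise_sd, size=image_size)
        stack[i] = np.clip(img, 0, 255).astype(np.uint8)
    return stack, FaceGroundTruth(labels=labels, intensity=intensity)


# ---------------------------------------------------------------------------
# open-field trajectory & locomotion

def gen_trajectory(
    duration_s: float = 600.0,
    frame_rate_hz: float = 20.0,
    mean_speed: float = 8.0,
    turn_concentration: float = 20.0,
    arena_cm: float = 40.0,
    seed: int = 0,
):
    """Correlated random walk in a square arena, reflected at the walls.

    Heading increments are von Mises with the given concentration (``inf``
    gives a straight path); step length is ``mean_speed / frame_rate_hz``.
    Returns a :class:`neuropipe.behavior.Trajectory` in cm at ``raw`` state.
    """
    from .behavior import Trajectory

    if arena_cm <= 0:
        raise ValueError("arena_cm must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate_hz))
    step = mean_speed / frame_rate_hz
    if np.isinf(turn_concentration):
        dtheta = np.zeros(n - 1)
    else:
        dtheta = rng.vonmises(0.0, turn_concentration, size=n - 1)
    theta = rng.uniform(0, 2 * np.pi)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = arena_cm / 2, arena_cm / 2
    for i in range(1, n):
        theta += dtheta[i - 1]
        nx = x[i - 1] + step * np.cos(theta)
        ny = y[i - 1] + step * np.sin(theta)
        # reflect at walls, flipping the matching heading component
        if nx < 0 or nx > arena_cm:
            nx = -nx if nx < 0 else 2 * arena_cm - nx
            theta = np.pi - theta
        if ny < 0 or ny > arena_cm:
            ny = -ny if ny < 0 else 2 * arena_cm - ny
            theta = -theta
        x[i], y[i] = nx, ny
    t = np.arange(n) / frame_rate_hz
    return Trajectory(t=t, x=x, y=y, frame_rate_hz=frame_rate_hz, state="raw")


def gen_locomotion(
    n_frames: int, frame_rate_hz: float = 30.0, seed: int = 0
) -> np.ndarray:
    """Nonnegative locomotion trace: rectified, smoothed random drive with
    intermittent bouts, unit standard deviation."""
    rng = np.random.default_rng(seed)
    drive = rng.standard_normal(n_frames)
    width = max(1, int(round(0.5 * frame_rate_hz)))
    kern = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    slow = np.convolve(drive, kern / kern.sum(), mode="same")
    loco = np.maximum(slow, 0.0)
    sd = loco.std()
    return loco / sd if sd > 0 else loco


# ---------------------------------------------------------------------------
# two-photon traces

def allocate_counts(fractions: list[float], n: int) -> list[int]:
    """Deterministic largest-remainder allocation of ``n`` items."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base


def gen_cell_traces(
    n_cells: int,
    locomotion: np.ndarray,
    frac_pos: float = 0.4,
    frac_neg: float = 0.2,
    gain: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Fluorescence traces coupled to a locomotion time series.

    Positive cells are ``+gain x locomotion + noise``, negative cells
    ``-gain x locomotion + noise``, the remainder pure noise.  With the
    locomotion trace at unit SD, ``gain / noise_sd`` is the coupling SNR.
    Returns the ``n_cells x n_frames`` matrix and per-cell labels.
    """
    locomotion = np.asarray(locomotion, dtype=float)
    if locomotion.size < 10:
        raise ValueError("locomotion trace must have at least 10 samples")
    if frac_pos + frac_neg > 1 + 1e-12:
        raise ValueError("frac_pos + frac_neg must not exceed 1")
    rng = np.random.default_rng(seed)
    n_pos, n_neg, n_none = allocate_counts(
        [frac_pos, frac_neg, 1.0 - frac_pos - frac_neg], n_cells
    )
    labels = ["positive"] * n_pos + ["negative"] * n_neg + ["none"] * n_none
    sign = np.array([1.0] * n_pos + [-1.0] * n_neg + [0.0] * n_none)
    traces = (
        sign[:, None] * gain * locomotion[None, :]
        + noise_sd * rng.standard_normal((n_cells, locomotion.size))
    )
    return traces, labels


# ---------------------------------------------------------------------------
# spike trains

@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit within a recording span."""

    unit_id: int
    times: np.ndarray
    span_s: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValueError("spike times must be sorted")
        if times.size and (times[0] < 0 or times[-1] > self.span_s):
            raise ValueError("spike times must lie within the recording span")
        object.__setattr__(self, "times", times)


SPIKE_CLASSES = ("ON", "deactivated", "OFF", "none")


def _rate_segments(design: StimulusDesign, cls: str, base: float, gain: float,
                   off_window_s: float = 0.8):
    """Piecewise-constant rate profile as (start, end, rate) segments."""
    changes = [(0.0, base)]
    for onset, dur, _ in design.events:
        if cls == "ON":
            changes += [(onset, base * gain), (onset + dur, base)]
        elif cls == "deactivated":
            changes += [(onset, base / gain), (onset + dur, base)]
        elif cls == "OFF":
            changes += [(onset + dur, base * gain),
                        (onset + dur + off_window_s, base)]
    changes.sort()
    segs = []
    for (t0, r), (t1, _) in zip(changes, changes[1:] + [(design.run_length_s, 0.0)]):
        if t1 > t0:
            segs.append((t0, t1, r))
    return segs


def gen_spike_trains(
    design: StimulusDesign,
    n_cells: int = 40,
    class_mix: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2),
    base_rate_hz: float = 10.0,
    mod_gain: float = 4.0,
    seed: int = 0,
) -> tuple[list[SpikeTrain], list[str]]:
    """Inhomogeneous Poisson trains with known response phenotypes.

    ``class_mix`` gives the (ON, deactivated, OFF, none) fractions, allocated
    deterministically.  ON cells fire at ``base x gain`` during stimulation,
    deactivated cells at ``base / gain``, OFF cells at ``base x gain`` for
    0-800 ms after stimulus offset, and "none" cells at a constant base rate.
    """
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    if base_rate_hz <= 0:
        raise ValueError("base_rate_hz must be positive")
    if mod_gain <= 1:
        raise ValueError("mod_gain must exceed 1, otherwise classes are "
                         "indistinguishable")
    rng = np.random.default_rng(seed)
    counts = allocate_counts(list(class_mix), n_cells)
    labels = [cls for cls, c in zip(SPIKE_CLASSES, counts) for _ in range(c)]
    trains = []
    for uid, cls in enumerate(labels):
        times = []
        for t0, t1, rate in _rate_segments(design, cls, base_rate_hz, mod_gain):
            n = rng.poisson(rate * (t1 - t0))
            times.append(rng.uniform(t0, t1, size=n))
        times = np.sort(np.concatenate(times)) if times else np.array([])
        trains.append(SpikeTrain(unit_id=uid, times=times,
                                 span_s=design.run_length_s))
    return trains, labels
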