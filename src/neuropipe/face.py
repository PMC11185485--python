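"""Facial-expression prototypes from histogram-of-oriented-gradients (HOG).

Every video frame (cropped to the face by the caller) is summarised by an
unsigned-gradient HOG descriptor — 32 pixels per cell, 1 cell per block,
8 orientation bins over [0, 180) degrees, L2 block normalisation — so the
descriptor is invariant to uniform illumination scaling.  A *neutral*
prototype is the mean descriptor over quiet baseline frames; *pleasure* /
*disgust* prototypes average the 10 tastant-period frames least correlated
with the neutral prototype.  Time-resolved Pearson correlation of each frame
with a prototype gives a similarity trace, and trial-level scores are
compared with a two-sided Wilcoxon rank-sum test.

Descriptor indices whose cells overlap a water-spout ROI are removed from
every frame before any correlation is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import hog as _sk_hog

from .design import StimulusDesign

__all__ = [
    "HogSeries",
    "EmotionPrototype",
    "SimilarityTrace",
    "TrialStats",
    "compute_hog",
    "neutral_prototype",
    "emotion_prototype",
    "similarity_trace",
    "trial_stats",
    "select_baseline_frames",
]


@dataclass
class HogSeries:
    """Per-frame HOG descriptors with the spout indices already removed."""

    descriptors: np.ndarray            # n_frames x d_kept
    cell_px: int
    n_bins: int
    n_cells: tuple[int, int]           # (rows, cols) of the cell grid
    excluded_indices: np.ndarray       # indices (into the full vector) removed

    @property
    def n_frames(self) -> int:
        return self.descriptors.shape[0]

    @property
    def d(self) -> int:
        return self.descriptors.shape[1]


@dataclass(frozen=True)
class EmotionPrototype:
    kind: str                           # neutral | pleasure | disgust
    vector: np.ndarray
    source_frames: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("neutral", "pleasure", "disgust"):
            raise ValueError(f"unknown prototype kind {self.kind!r}")


@dataclass
class SimilarityTrace:
    """Per-frame Pearson correlation with one prototype (NaN = undefined)."""

    values: np.ndarray
    kind: str
    normalized: np.ndarray | None = None


def compute_hog(
    frames: np.ndarray,
    cell_px: int = 32,
    n_bins: int = 8,
    spout_mask: np.ndarray | None = None,
) -> HogSeries:
    """Unsigned-gradient HOG descriptors for a frame stack.

    Frame dimensions that are not multiples of ``cell_px`` lose their
    trailing pixels (with a warning).  ``spout_mask`` is a boolean pixel mask;
    any cell overlapping it has its ``n_bins`` descriptor entries removed
    from every frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    h, w = frames.shape[1:]
    if h < cell_px or w < cell_px:
        raise ValueError("frames must be at least one cell in each dimension")
    hc, wc = (h // cell_px) * cell_px, (w // cell_px) * cell_px
    if (hc, wc) != (h, w):
        warnings.warn(
            f"frame size {h}x{w} is not a multiple of cell_px={cell_px}; "
            f"trailing pixels dropped (using {hc}x{wc})"
        )
    ncy, ncx = hc // cell_px, wc // cell_px
    excluded = np.array([], dtype=int)
    if spout_mask is not None:
        spout_mask = np.asarray(spout_mask, dtype=bool)[:hc, :wc]
        bad_cells = (
            spout_mask.reshape(ncy, cell_px, ncx, cell_px).any(axis=(1, 3))
        )
        cells = np.flatnonzero(bad_cells.ravel())
        excluded = (cells[:, None] * n_bins + np.arange(n_bins)[None, :]).ravel()
    keep = np.setdiff1d(np.arange(ncy * ncx * n_bins), excluded)
    desc = np.empty((frames.shape[0], keep.size))
    for i, frame in enumerate(frames):
        full = _sk_hog(
            frame[:hc, :wc],
            orientations=n_bins,
            pixels_per_cell=(cell_px, cell_px),
            cells_per_block=(1, 1),
            block_norm="L2",
            feature_vector=True,
        )
        desc[i] = full[keep]
    return HogSeries(
        descriptors=desc,
        cell_px=cell_px,
        n_bins=n_bins,
        n_cells=(ncy, ncx),
        excluded_indices=excluded,
    )


def _pearson_rows(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each row against ``v``; NaN where either is constant."""
    rows = rows - rows.mean(axis=1, keepdims=True)
    v = v - v.mean()
    num = rows @ v
    denom = np.sqrt((rows * rows).sum(axis=1) * (v * v).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def neutral_prototype(hog: HogSeries, baseline_frames: np.ndarray) -> EmotionPrototype:
    """Mean descriptor over quiet pre-stimulus baseline frames."""
    idx = np.asarray(baseline_frames, dtype=int)
    if idx.size == 0:
        raise ValueError("baseline_frames must be nonempty")
    return EmotionPrototype(
        kind="neutral",
        vector=hog.descriptors[idx].mean(axis=0),
        source_frames=np.sort(idx),
    )


def emotion_prototype(
    hog: HogSeries,
    neutral: EmotionPrototype,
    tastant_frames: np.ndarray,
    kind: str = "disgust",
    n_select: int = 10,
) -> EmotionPrototype:
    """Average the ``n_select`` tastant frames least correlated with neutral.

    Ties in the correlation are broken toward the earlier frame index.
    """
    idx = np.asarray(tastant_frames, dtype=int)
    if idx.size < n_select:
        raise ValueError(
            f"need at least n_select={n_select} tastant frames, got {idx.size}"
        )
    idx = np.sort(idx)
    r = _pearson_rows(hog.descriptors[idx], neutral.vector)
    order = np.argsort(r, kind="stable")      # stable: earlier frame wins ties
    chosen = idx[order[:n_select]]
    return EmotionPrototype(
        kind=kind,
        vector=hog.descriptors[chosen].mean(axis=0),
        source_frames=np.sort(chosen),
    )


def similarity_trace(hog: HogSeries, prototype: EmotionPrototype) -> SimilarityTrace:
    """Per-frame Pearson correlation with a prototype.

    Zero-variance frames yield NaN (recorded as missing, not zero).
    """
    if hog.d != prototype.vector.size:
        raise ValueError("descriptor dimension does not match prototype")
    r = _pearson_rows(hog.descriptors, prototype.vector)
    return SimilarityTrace(values=r, kind=prototype.kind)


@dataclass
class TrialStats:
    scores: pd.DataFrame            # trial, group, score
    statistic: float | None
    pvalue: float | None
    normalized: np.ndarray


def _window_mean(values: np.ndarray, idx: np.ndarray) -> float:
    vals = values[idx]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else np.nan


def trial_stats(
    trace: SimilarityTrace,
    design: StimulusDesign,
    baseline_windows: list[np.ndarray],
    frame_rate_hz: float,
) -> TrialStats:
    """Per-trial mean similarity and a tastant-vs-baseline rank-sum test.

    The trace is min-max normalised to [0, 1] per run for display; the test
    (two-sided Wilcoxon rank-sum / Mann-Whitney) runs on the raw per-trial
    mean correlations.
    """
    n = trace.values.size
    t = np.arange(n) / frame_rate_hz
    rows = []
    for i, (onset, dur, cond) in enumerate(design.events):
        idx = np.flatnonzero((t >= onset) & (t < onset + dur))
        rows.append((i, "tastant", _window_mean(trace.values, idx)))
    for i, win in enumerate(baseline_windows):
        rows.append((i, "baseline", _window_mean(trace.values, np.asarray(win, int))))
    scores = pd.DataFrame(rows, columns=["trial", "group", "score"])
    tast = scores.loc[scores.group == "tastant", "score"].dropna().to_numpy()
    base = scores.loc[scores.group == "baseline", "score"].dropna().to_numpy()
    if tast.size < 2 or base.size < 2:
        warnings.warn("fewer than 2 trials per group; rank-sum test skipped")
        stat = p = None
    else:
        res = stats.mannwhitneyu(tast, base, alternative="two-sided",
                                 method="exact" if (tast.size + base.size) <= 25
                                 else "asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    finite = trace.values[~np.isnan(trace.values)]
    if finite.size and finite.max() > finite.min():
        norm = (trace.values - finite.min()) / (finite.max() - finite.min())
    else:
        norm = np.zeros_like(trace.values)
    trace.normalized = norm
    return TrialStats(scores=scores, statistic=stat, pvalue=p, normalized=norm)


def select_baseline_frames(
    frames: np.ndarray,
    design: StimulusDesign,
    frame_rate_hz: float,
    window_s: float = 2.0,
    quantile: float = 0.10,
) -> np.ndarray:
    """Heuristic stand-in for manual quiet-baseline selection.

    Picks pre-stimulus frames whose frame-difference energy falls below the
    given quantile — a proxy for "no locomotion and minimal orofacial
    movement", which real analyses determine from behaviour.  Only frames at
    least ``window_s`` before every event onset are eligible.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    t = np.arange(n) / frame_rate_hz
    eligible = np.ones(n, dtype=bool)
    for onset, dur, _ in design.events:
        eligible &= (t < onset - window_s) | (t >= onset + dur + window_s)
    diff = np.zeros(n)
    diff[1:] = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    cand = np.flatnonzero(eligible)
    if cand.size == 0:
        raise ValueError("no eligible pre-stimulus frames")
    cut = np.quantile(diff[cand], quantile)
    chosen = cand[diff[cand] <= cut]
    return chosen
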