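"""Two-photon ROI-trace analysis: QC, population component, classification.

Extracted fluorescence traces (one row per cell) pass a skewness QC — Ca2+
transients make genuine somatic traces strongly right-skewed, so cells with
sample skewness <= 2 are dropped.  The population's first principal
component (first right singular vector of the cell x time matrix) summarises
shared dynamics and is correlated with the locomotion trace, as is each
individual cell; per-cell correlation p-values are Benjamini-Hochberg
corrected and thresholded at p < 0.001, with the surviving cells labelled
positive or negative by the sign of r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fus_activation import moving_average

__all__ = [
    "CellTraceMatrix",
    "qc_filter",
    "population_pc1",
    "classify_cells",
]


@dataclass
class CellTraceMatrix:
    """Fluorescence traces, one row per detected cell."""

    traces: np.ndarray                 # n_cells x n_frames
    frame_rate_hz: float = 30.0
    cell_ids: np.ndarray | None = None
    qc_passed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, float))
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.traces.shape[0])

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]


def qc_filter(
    cells: CellTraceMatrix,
    skew_min: float = 2.0,
    manual_exclude: np.ndarray | None = None,
) -> CellTraceMatrix:
    """Keep transient-rich cells: sample skewness strictly above ``skew_min``.

    ``manual_exclude`` honours caller-provided exclusions (e.g. traces with
    sudden jumps from z-displacement, judged by eye in real data).
    """
    if cells.n_cells < 1:
        raise ValueError("need at least one cell")
    skw = stats.skew(cells.traces, axis=1)
    keep = skw > skew_min
    if manual_exclude is not None:
        keep &= ~np.isin(cells.cell_ids, np.asarray(manual_exclude))
    if not keep.any():
        warnings.warn("QC removed every cell; returning an empty matrix")
    return CellTraceMatrix(
        traces=cells.traces[keep].reshape(-1, cells.traces.shape[1]),
        frame_rate_hz=cells.frame_rate_hz,
        cell_ids=cells.cell_ids[keep],
        qc_passed=keep,
    )


def population_pc1(
    cells: CellTraceMatrix, smooth_s: float = 0.5, center: bool = True
) -> np.ndarray:
    """First right singular vector of the cell x time matrix, smoothed.

    Traces are mean-centered per cell before the SVD (disable with
    ``center=False``); the singular-vector sign is fixed by positive
    correlation with the population-mean trace, and the result is
    moving-average smoothed over ``smooth_s``.
    """
    if cells.n_cells < 2:
        raise ValueError("need at least 2 cells for a population component")
    x = cells.traces - cells.traces.mean(axis=1, keepdims=True) if center \
        else cells.traces
    if not np.any(x):
        raise ValueError("rank-0 matrix: traces are constant")
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc1 = vt[0]
    pop_mean = cells.traces.mean(axis=0)
    if np.corrcoef(pc1, pop_mean)[0, 1] < 0:
        pc1 = -pc1
    win = max(1, int(round(smooth_s * cells.frame_rate_hz)))
    return moving_average(pc1, win)


def classify_cells(
    cells: CellTraceMatrix,
    locomotion: np.ndarray,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Label each cell positive / negative / none by locomotion correlation.

    Per cell, Pearson r against the locomotion trace with its t-distribution
    p-value; BH correction across cells; adjusted p < ``alpha`` classifies by
    the sign of r, otherwise "none".  Locomotion must already be resampled to
    the imaging frame rate.  Constant cells are "none" (with a warning).
    """
    locomotion = np.asarray(locomotion, float)
    if locomotion.size != cells.traces.shape[1]:
        raise ValueError("locomotion length must match the trace length "
                         "(resample to the imaging rate first)")
    n = locomotion.size
    x = cells.traces - cells.traces.mean(axis=1, keepdims=True)
    v = locomotion - locomotion.mean()
    denom = np.sqrt((x * x).sum(axis=1) * (v * v).sum())
    const = denom == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant cell trace(s) classified 'none'")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(~const, (x @ v) / np.where(denom == 0, 1, denom), 0.0)
    r = np.clip(r, -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(dof / np.maximum(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    p[const] = 1.0
    rej, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    label = np.where(rej & (r > 0), "positive",
                     np.where(rej & (r < 0), "negative", "none"))
    return pd.DataFrame(
        {"cell": cells.cell_ids, "r": r, "p": p, "p_adj": p_adj,
         "class": label}
    )
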