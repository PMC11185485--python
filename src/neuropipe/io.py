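"""Shared readers/writers, run configuration, and the pipeline runner.

On-disk conventions:

- power-Doppler series: HDF5 with datasets ``/doppler`` (voxels x frames),
  ``/t`` (s) and ``/geometry`` (voxel grid shape), plus stage / frame-rate
  attributes;
- image stacks: multi-page TIFF;
- stimulus designs, trajectories, spike times, labels, reports: CSV with
  documented headers.

:class:`RunConfig` gathers every tunable of the pipeline with its default
value; :func:`run_pipeline` executes a named stage chain deterministically
under the config seed and writes a JSON provenance record alongside the
outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .design import StimulusDesign
from .fus_preprocess import FusSeries

__all__ = [
    "RunConfig",
    "save_fus_series",
    "load_fus_series",
    "save_stack",
    "load_stack",
    "save_design",
    "load_design",
    "save_trajectory",
    "load_trajectory",
    "save_spike_trains",
    "load_spike_trains",
    "run_pipeline",
    "file_digest",
]


# ---------------------------------------------------------------------------
# readers / writers

def save_fus_series(path: str | Path, series: FusSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("doppler", data=series.doppler)
        f.create_dataset("t", data=series.t)
        f.create_dataset("geometry", data=np.asarray(series.voxel_shape, int))
        f.attrs["stage"] = series.stage
        f.attrs["frame_rate_hz"] = -1.0 if series.frame_rate_hz is None else series.frame_rate_hz
        f.attrs["voxel_pitch_um"] = series.voxel_pitch_um


def load_fus_series(path: str | Path) -> FusSeries:
    with h5py.File(path, "r") as f:
        fr = float(f.attrs["frame_rate_hz"])
        return FusSeries(
            doppler=f["doppler"][()],
            t=f["t"][()],
            frame_rate_hz=None if fr < 0 else fr,
            voxel_shape=tuple(int(v) for v in f["geometry"][()]),
            voxel_pitch_um=tuple(f.attrs["voxel_pitch_um"]),
            stage=str(f.attrs["stage"]),
        )


def save_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, stack)


def load_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_design(path: str | Path, design: StimulusDesign) -> None:
    df = design.to_frame()
    df.attrs = {}
    with open(path, "w") as f:
        f.write(f"# run_length_s={design.run_length_s}\n")
        df.to_csv(f, index=False)


def load_design(path: str | Path) -> StimulusDesign:
    with open(path) as f:
        header = f.readline()
        run_length = float(header.strip().split("=", 1)[1])
        df = pd.read_csv(f)
    return StimulusDesign.from_frame(df, run_length)


def save_trajectory(path: str | Path, traj) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(path, index=False)


def load_trajectory(path: str | Path, frame_rate_hz: float):
    from .behavior import Trajectory

    df = pd.read_csv(path)
    return Trajectory(t=df.t.to_numpy(), x=df.x.to_numpy(), y=df.y.to_numpy(),
                      frame_rate_hz=frame_rate_hz, state="raw")


def save_spike_trains(path: str | Path, trains) -> None:
    rows = [(tr.unit_id, t, tr.span_s) for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=["unit", "t", "span_s"]).to_csv(path, index=False)


def load_spike_trains(path: str | Path):
    from .synth import SpikeTrain

    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit"):
        trains.append(SpikeTrain(unit_id=int(uid),
                                 times=np.sort(grp.t.to_numpy()),
                                 span_s=float(grp.span_s.iloc[0])))
    return trains


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default value.

    Defaults mirror the published analysis settings: scrub multiplier 4.44,
    high-pass cutoff 0.056 Hz (order 5), 4-frame temporal smoothing, HOG with
    32-px cells and 8 bins selecting 10 frames per prototype, 1.2-s
    tortuosity window, 0.5-s behavioural smoothing, 40-s trial baseline with
    z-threshold 2, skewness threshold 2, significance levels 0.05 (voxel /
    region) and 0.001 (cell), 1-ms bins with a 10-ms kernel, 70-ms smoothing,
    4.5-s ephys baseline, correlation threshold 0.2 and an 800-ms OFF window.
    """

    seed: int = 0
    # fUS preprocessing
    target_hz: float = 2.0
    baseline_n_frames: int = 11          # presets: 11 (short ITI) or 70 (long)
    cutoff_hz: float = 0.056
    filter_order: int = 5
    scrub_k: float = 4.44
    skip_pc: bool = False                # PC removal is the awake-only step
    # fUS activation
    hrf_peak_s: float = 1.5
    hrf_shape: float = 3.0
    smooth_frames_n: int = 4
    alpha_voxel: float = 0.05
    alpha_region: float = 0.05
    # face
    cell_px: int = 32
    n_bins: int = 8
    n_select: int = 10
    # behavior
    downsample: int = 3
    smooth_s: float = 0.5
    tortuosity_window_s: float = 1.2
    trial_baseline_s: float = 40.0
    z_threshold: float = 2.0
    # two-photon
    skew_min: float = 2.0
    alpha_cell: float = 0.001
    # ephys
    bin_ms: float = 1.0
    kernel_sd_ms: float = 10.0
    smooth_ms: float = 70.0
    ephys_baseline_s: float = 4.5
    r_thresh: float = 0.2
    off_window_ms: float = 800.0

    def validate(self) -> None:
        positive = [
            "target_hz", "baseline_n_frames", "cutoff_hz", "filter_order",
            "scrub_k", "hrf_peak_s", "smooth_frames_n", "cell_px", "n_bins",
            "n_select", "downsample", "smooth_s", "tortuosity_window_s",
            "trial_baseline_s", "bin_ms", "kernel_sd_ms", "smooth_ms",
            "ephys_baseline_s", "r_thresh", "off_window_ms",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be positive "
                                 f"(got {getattr(self, name)})")
        for name in ("alpha_voxel", "alpha_region", "alpha_cell"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"parameter {name!r} must lie in (0, 1)")
        if self.hrf_shape <= 1:
            raise ValueError("parameter 'hrf_shape' must exceed 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline runner

def run_pipeline(config: RunConfig, stage: str, out_dir: str | Path,
                 n_voxels: int = 200, n_sessions: int = 3) -> dict:
    """Execute a named stage chain on synthetic data and write its artifacts.

    ``stage="fus"`` runs synth -> preprocess -> GLM -> group significance and
    writes the series, T-scores, significance map and a JSON provenance
    record.  Everything is deterministic under ``config.seed``.
    """
    from . import fus_activation as fa
    from . import fus_preprocess as fp
    from . import synth

    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stage != "fus":
        raise ValueError(f"unknown pipeline stage {stage!r} (available: 'fus')")

    design = synth.gen_stimulus_design("visual_block", seed=config.seed)
    hrf = fa.make_hrf(config.target_hz, config.hrf_peak_s, config.hrf_shape)
    tmaps = []
    outputs = {}
    for s in range(n_sessions):
        series, truth = synth.gen_fus_series(
            design, n_voxels=n_voxels, frame_rate_hz=config.target_hz,
            n_artifacts=3, global_amp=0.02, seed=config.seed * 1000 + s,
        )
        raw_path = out_dir / f"session{s}_raw.h5"
        save_fus_series(raw_path, series)
        pre = fp.interpolate_to_rate(series, config.target_hz)
        pre = fp.delta_i_over_i(pre, design, config.baseline_n_frames)
        pre = fp.highpass(pre, config.cutoff_hz, config.filter_order)
        if config.skip_pc:
            pre.stage = "pc_removed"
        else:
            pre = fp.remove_first_pc(pre)
        pre, report = fp.scrub_motion(pre, config.scrub_k)
        report.to_frame().to_csv(out_dir / f"session{s}_scrub.csv", index=False)
        smoothed = fa.smooth_frames(pre, config.smooth_frames_n)
        X, _ = fa.build_design_matrix(design, hrf, pre.t, pool_conditions=True)
        tmaps.append(fa.fit_glm(smoothed, X))
        outputs[f"session{s}_raw"] = file_digest(raw_path)
    sig = fa.group_significance(tmaps, alpha=config.alpha_voxel)
    sig_path = out_dir / "significance.h5"
    with h5py.File(sig_path, "w") as f:
        f.create_dataset("t", data=sig.t)
        f.create_dataset("p_adj", data=sig.p_adj)
        f.create_dataset("significant", data=sig.significant)
        f.create_dataset("tscores", data=np.vstack([m.tscore for m in tmaps]))
    outputs["significance"] = file_digest(sig_path)
    provenance = {
        "stage": stage,
        "config": asdict(config),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "outputs": outputs,
    }
    with open(out_dir / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=2, sort_keys=True)
    return provenance
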