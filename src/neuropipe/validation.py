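"""Ground-truth recovery experiments on synthetic data.

Each function generates data with the :mod:`neuropipe.synth` module, runs
the corresponding analysis stage, and scores the result against the known
ground truth.  They are the package's own end-to-end validation battery —
the same experiments the test suite asserts on and the acceptance script
reports.

Problem sizes (500 voxels, 5 sessions, 60 units, 200 cells, 10 x 20
trajectories) are chosen so the whole battery runs in well under ten minutes
on one CPU while keeping Monte-Carlo error on every reported fraction below
a couple of percent.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from . import behavior as bh
from . import ephys as ep
from . import face as fc
from . import fus_activation as fa
from . import fus_preprocess as fp
from . import synth
from . import twophoton as tp

__all__ = [
    "scrub_recovery",
    "glm_recovery",
    "glm_null_calibration",
    "face_selectivity",
    "tortuosity_battery",
    "ephys_recovery",
    "twophoton_recovery",
    "twophoton_null_calibration",
]


def _dii(series, design, baseline_n_frames=11):
    s = fp.interpolate_to_rate(series, series.frame_rate_hz)
    return fp.delta_i_over_i(s, design, baseline_n_frames)


def scrub_recovery(seed: int = 0, n_voxels: int = 500, n_artifacts: int = 20
                   ) -> dict:
    """Sensitivity / false-flag rate of MAD scrubbing on injected artifacts.

    Artifacts are globally shared spike frames; scrubbing is evaluated on the
    ΔI/I series directly (the first-PC stage would itself absorb globally
    coherent spikes, so it is bypassed here to score the MAD rule alone).
    """
    design = synth.gen_stimulus_design("visual_block", seed=seed)
    series, truth = synth.gen_fus_series(design, n_voxels=n_voxels,
                                         n_artifacts=n_artifacts, seed=seed)
    s = _dii(series, design)
    s.stage = "pc_removed"
    _, report = fp.scrub_motion(s)
    art = truth.artifact_frames
    tp_count = sum(np.isin(f, art).sum() for f in report.flagged)
    fp_count = sum((~np.isin(f, art)).sum() for f in report.flagged)
    n_clean = (s.n_frames - art.size) * n_voxels
    return {
        "sensitivity": tp_count / (art.size * n_voxels),
        "false_flag_rate": fp_count / n_clean,
        "n": n_voxels * s.n_frames,
        "thresholds": report.threshold,
        "flagged": report.flagged,
        "series": s,
    }


def _one_glm_experiment(seed: int, n_voxels: int, n_sessions: int,
                        beta: float, noise_sd: float, alpha: float):
    rng = np.random.default_rng(seed)
    design = synth.gen_stimulus_design("visual_block", seed=seed)
    hrf = fa.make_hrf(2.0)
    mask = np.zeros(n_voxels, bool)
    mask[rng.choice(n_voxels, n_voxels // 10, replace=False)] = True
    tmaps = []
    for k in range(n_sessions):
        series, _ = synth.gen_fus_series(
            design, n_voxels=n_voxels, beta=beta, noise_sd=noise_sd,
            active_mask=mask, seed=int(rng.integers(2**31)))
        s = _dii(series, design)
        X, _ = fa.build_design_matrix(design, hrf, s.t, pool_conditions=True)
        tmaps.append(fa.fit_glm(fa.smooth_frames(s, 4), X))
    sig = fa.group_significance(tmaps, alpha=alpha)
    return sig, mask


def glm_recovery(seed: int = 0, n_replicates: int = 5, n_voxels: int = 500,
                 n_sessions: int = 5, beta: float = 0.03,
                 noise_sd: float = 0.01, alpha: float = 0.05) -> dict:
    """Active-voxel recovery of the group GLM at beta = 3x noise SD.

    Sensitivity and observed FDR are means over ``n_replicates`` independent
    experiments of ``n_sessions`` sessions sharing one active mask (FDR is an
    expectation, so a single experiment only gives a noisy draw of it).
    """
    sens, fdr = [], []
    for r in range(n_replicates):
        sig, mask = _one_glm_experiment(seed * 1000 + r, n_voxels, n_sessions,
                                        beta, noise_sd, alpha)
        sens.append(sig.significant[mask].mean())
        fdr.append((sig.significant & ~mask).sum()
                   / max(1, sig.significant.sum()))
    return {"sensitivity": float(np.mean(sens)),
            "observed_fdr": float(np.mean(fdr)),
            "n": n_replicates * n_voxels}


def glm_null_calibration(seed: int = 0, n_seeds: int = 50,
                         n_voxels: int = 500, n_sessions: int = 3) -> dict:
    """Fraction of voxels declared significant when no signal exists."""
    fracs = []
    for r in range(n_seeds):
        sig, _ = _one_glm_experiment(seed * 7000 + r, n_voxels, n_sessions,
                                     beta=0.0, noise_sd=0.01, alpha=0.05)
        fracs.append(sig.significant.mean())
    return {"significant_fraction": float(np.mean(fracs)),
            "n": n_seeds * n_voxels}


def face_selectivity(seed: int = 0, isi_s: float = 10.0,
                     image_size: tuple[int, int] = (64, 64)) -> dict:
    """Discriminability of the prototype pipeline on synthetic face video.

    Builds per-"mouse" prototypes (neutral from quiet baselines, disgust from
    the quinine run, pleasure from the sucrose run) and scores how well the
    disgust similarity separates quinine frames from baseline frames (AUC),
    and whether the pleasure similarity spuriously separates them.
    """
    fr = 20.0
    dq = synth.gen_tastant_design("quinine", isi_s=isi_s, baseline_s=10.0)
    ds = synth.gen_tastant_design("sucrose", isi_s=isi_s, baseline_s=10.0)
    stq, gtq = synth.gen_face_sequence(dq, image_size=image_size, seed=seed)
    sts, _ = synth.gen_face_sequence(ds, image_size=image_size, seed=seed + 1)
    hq, hs = fc.compute_hog(stq), fc.compute_hog(sts)
    t = np.arange(stq.shape[0]) / fr
    baseq = fc.select_baseline_frames(stq, dq, fr)
    bases = fc.select_baseline_frames(sts, ds, fr)
    neutral_q = fc.neutral_prototype(hq, baseq)
    neutral_s = fc.neutral_prototype(hs, bases)
    disgust = fc.emotion_prototype(
        hq, neutral_q, np.flatnonzero(dq.boxcar(t) > 0), kind="disgust")
    pleasure = fc.emotion_prototype(
        hs, neutral_s, np.flatnonzero(ds.boxcar(t) > 0), kind="pleasure")
    sim_d = fc.similarity_trace(hq, disgust).values
    sim_p = fc.similarity_trace(hq, pleasure).values
    is_quinine = np.array([l == "disgust" for l in gtq.labels])
    in_baseline = np.zeros(t.size, bool)
    in_baseline[baseq] = True
    sel = is_quinine | in_baseline
    return {
        "disgust_auc": float(roc_auc_score(is_quinine[sel], sim_d[sel])),
        "pleasure_auc_on_quinine": float(roc_auc_score(is_quinine[sel],
                                                       sim_p[sel])),
        "n": int(sel.sum()),
    }


def tortuosity_battery(seed: int = 0, n_levels: int = 10, n_seeds: int = 20
                       ) -> dict:
    """Geometry oracles and the concentration-vs-straightness ordering."""
    # straight-line limit
    straight = synth.gen_trajectory(duration_s=30, frame_rate_hz=20,
                                    mean_speed=5, turn_concentration=np.inf,
                                    arena_cm=1000, seed=seed)
    _, med_straight = bh.tortuosity(bh.preprocess_trajectory(straight))
    # sampled semicircle spanning exactly one window
    fr = 20.0
    n_side = int(round(1.2 * fr / 2))
    ang = np.linspace(0, np.pi, 2 * n_side + 1)
    semi = bh.Trajectory(t=np.arange(ang.size) / fr, x=10 * np.cos(ang),
                         y=10 * np.sin(ang), frame_rate_hz=fr,
                         speed=np.full(ang.size, 5.0), state="smoothed")
    tort, _ = bh.tortuosity(semi)
    semicircle_ratio = float(tort[n_side])
    # monotone ordering across turning concentrations
    kappas = np.logspace(0, 2.5, n_levels)
    medians = []
    for kappa in kappas:
        vals = []
        for s in range(n_seeds):
            traj = synth.gen_trajectory(duration_s=60, frame_rate_hz=20,
                                        turn_concentration=float(kappa),
                                        seed=seed * 500 + s)
            _, m = bh.tortuosity(bh.preprocess_trajectory(traj))
            vals.append(m)
        medians.append(float(np.median(vals)))
    rho = float(spearmanr(kappas, medians).statistic)
    return {
        "straight_median": float(med_straight),
        "semicircle_ratio": semicircle_ratio,
        "concentration_spearman": rho,
        "n": n_levels * n_seeds,
    }


def ephys_recovery(seed: int = 0, n_cells: int = 60) -> dict:
    """Response-phenotype recovery at gain 4, base 10 Hz, 15 trials."""
    design = synth.gen_stimulus_design("opto_ephys", seed=seed)
    trains, labels = synth.gen_spike_trains(
        design, n_cells=n_cells, class_mix=(0.3, 0.3, 0.3, 0.1),
        base_rate_hz=10.0, mod_gain=4.0, seed=seed)
    pred = []
    for tr in trains:
        avg = ep.trial_average_z(ep.firing_rate(tr), design)
        pred.append(ep.classify_response(avg)[0])
    pred, labels = np.array(pred), np.array(labels)
    out = {"n": n_cells}
    for cls in ("ON", "deactivated", "OFF"):
        sel = labels == cls
        out[f"{cls.lower()}_recovery"] = float((pred[sel] == cls).mean())
    return out


def twophoton_recovery(seed: int = 0, n_cells: int = 200) -> dict:
    """Locomotion-coupling label recovery at coupling SNR 2."""
    loco = synth.gen_locomotion(2700, 30.0, seed=seed)
    traces, labels = synth.gen_cell_traces(n_cells, loco, frac_pos=0.4,
                                           frac_neg=0.2, gain=1.0,
                                           noise_sd=0.5, seed=seed)
    cells = tp.CellTraceMatrix(traces=traces, frame_rate_hz=30.0)
    pred = tp.classify_cells(cells, loco)["class"].to_numpy()
    labels = np.array(labels)
    coupled = labels != "none"
    return {
        "coupled_recovery": float((pred[coupled] == labels[coupled]).mean()),
        "none_misclassified": float((pred[~coupled] != "none").mean()),
        "n": n_cells,
    }


def twophoton_null_calibration(seed: int = 0, n_seeds: int = 50,
                               n_cells: int = 1000, n_frames: int = 600
                               ) -> dict:
    """Rate at which pure-noise cells survive the BH p < 0.001 threshold."""
    loco = synth.gen_locomotion(n_frames, 30.0, seed=seed)
    bad = 0
    for s in range(n_seeds):
        traces, _ = synth.gen_cell_traces(n_cells, loco, frac_pos=0.0,
                                          frac_neg=0.0, seed=seed * 300 + s)
        cells = tp.CellTraceMatrix(traces=traces, frame_rate_hz=30.0)
        pred = tp.classify_cells(cells, loco)["class"]
        bad += int((pred != "none").sum())
    return {"non_none_rate": bad / (n_seeds * n_cells),
            "n": n_seeds * n_cells}
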