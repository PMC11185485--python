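# Methods

This note documents the models, parameter conventions and design choices
behind `neuropipe`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model for functional ultrasound

A power-Doppler voxel is modelled as

    I_v(t) = b_v · (1 + β_v x(t) + g·m(t) + d(t) + ε_v(t)),

where `b_v` is a positive baseline intensity, `x(t)` is the stimulus boxcar
convolved with the hemodynamic response function (HRF) and normalised to
unit peak, `β_v` the peak relative response (ΔI/I units; zero for inactive
voxels), `m(t)` a smooth global "motion" component shared by all voxels,
`d(t)` a slow linear drift, and `ε_v` white Gaussian noise.  Motion-artifact
frames receive additive positive spikes of at least 8× the per-voxel MAD of
the relative signal, so the scrubbing rule is obliged to flag them.  The
generator returns the active mask, true amplitudes, artifact frames and the
global component, which is what makes recovery scoring possible.

### HRF

No shape parameters are canonical for rodent power-Doppler responses, so the
kernel is a gamma density with its mode (peak time) at 1.5 s and shape 3 —
fast rodent cerebrovascular dynamics — sampled at the frame rate, normalised
to unit peak and truncated below 1% of peak.  Both parameters are exposed
(`make_hrf(frame_rate_hz, peak_time_s, shape)`).  The synthetic generator
uses the same kernel as the activation model on purpose: recovery
experiments test the estimation machinery, not HRF mis-specification, and no
experiment here can arbitrate the true in vivo kernel.

### Preprocessing conventions

- **Stage ordering** is enforced: raw → interpolated → ΔI/I → filtered →
  PC-removed → scrubbed.  Frame indexing is 0-based and all time windows are
  half-open `[onset, offset)`.
- **ΔI/I segmentation.**  Each event's baseline is the `baseline_n_frames`
  frames (presets 11 or 70) immediately before onset.  Segment boundaries
  are not fully determined by the published description; here each event's
  normalisation extends from its onset until the next event's baseline
  window begins, and the pre-first-event period reuses the first baseline.
- **High-pass filter.**  The 0.056 Hz fifth-order Butterworth is applied
  forward–backward (zero phase) so the slow response is not lagged; the
  magnitude order therefore doubles.  Note the consequence: for a 24-s block
  design the stimulus fundamental (0.042 Hz) lies *below* the cutoff and is
  attenuated roughly twenty-fold, leaving mostly harmonics.  This is a real
  property of the published parameterisation, not an implementation choice.
- **MAD convention.**  "Median + absolute deviation × 4.44" is read as the
  unscaled median absolute deviation (no 1.4826 factor); 4.44·MAD ≈ 3σ for
  Gaussian data, which matches standard scrubbing practice.  Only upward
  deviations are flagged (the rule is one-sided by construction).  Flagged
  frames are linearly interpolated across unflagged neighbours; edge frames
  take the nearest unflagged value.  A defensive warning exists for voxels
  with >50% flagged frames, though a median-anchored threshold cannot
  actually exceed 50%.
- **First-PC removal** operates on the entire session matrix (not
  per-trial) and is skippable (`skip_pc`) for anesthetized sessions.

### Activation statistics

Per voxel, OLS with an intercept plus one HRF-convolved regressor per
condition (or a pooled regressor); T = β̂/SE.  Group inference is a
two-sided one-sample t-test of session T-scores against zero with
Benjamini–Hochberg correction across voxels (the step-up variant; only
"FDR-corrected" is canonical).  Degenerate voxels: identical zero T-scores
give p = 1; identical nonzero T-scores give p = 0 and are flagged.  Region
correlation uses the raw stimulus boxcar ("stimulus timing"), with an option
to use the convolved regressor instead.  The display mask hides samples with
ΔI/I < 1.75% and voxels with mean baseline ΔI/I > 5%, both strict
inequalities.

## Facial-expression pipeline

HOG parameters: 32-px cells, one cell per block, 8 unsigned orientation bins
(over [0°, 180°)), plain L2 block normalisation — which makes descriptors
invariant to uniform illumination scaling.  Cells overlapping the water-spout
ROI are removed from every frame's descriptor before any correlation.
Prototype selection breaks correlation ties toward earlier frames.  The
"normalised" similarity used for display is per-run min–max scaling to
[0, 1]; all statistics run on raw Pearson r.  Trial comparison uses the
two-sided Wilcoxon rank-sum (Mann–Whitney) test, exact for ≤ 25 pooled
trials.  Quiet-baseline discovery ("no locomotion, minimal orofacial
movement") is caller-provided in real use; `select_baseline_frames` offers a
synthetic stand-in that takes pre-stimulus frames below the 10th percentile
of frame-difference energy.

The synthetic face is deliberately schematic: an ellipse head, ear, snout
and whisker strokes on a noisy background, whose ear/snout/whisker
parameters deform continuously (ramp 0.25 s) toward a pleasure or disgust
configuration during tastant events and jitter around neutral otherwise.
It exercises the discriminative behaviour of the HOG prototype pipeline —
nothing about photorealism, eye or whisker kinematics.

## Behaviour

Open-field positions are decimated by 3, moving-average smoothed over 0.5 s,
and speed is displacement × output rate computed *after* smoothing.
Percentiles use linear interpolation between order statistics.  Tortuosity
windows (1.2 s) are centred; edge-truncated windows are dropped, zero-chord
windows are undefined and excluded, and the path/chord ratio is ≥ 1 up to
discretisation.  The trial-split boundary z = 2 is assigned to
"no locomotion" (the published rule leaves exactly-2 unassigned).

The trajectory generator is a correlated random walk: fixed step length
`mean_speed/frame_rate`, von Mises heading increments whose concentration κ
controls straightness, reflecting walls.  Defaults (10 min at 20 Hz, 40-cm
arena, 8 cm/s) mirror a standard open-field session.

## Two-photon and electrophysiology

Two-photon traces are mean-centred per cell before the SVD (flag to
disable); the first right singular vector's sign is fixed by positive
correlation with the population mean.  Per-cell correlations use the raw
cell traces against the locomotion trace (smoothing is specified only for
the population component).  Manual jump rejection is replaced by an explicit
exclusion-list argument — no automatic detector is claimed.

Firing rates: 1-ms bins convolved with a unit-area Gaussian (SD 10 ms)
truncated at ±4 SD and renormalised, so the trace integrates to the spike
count.  Classification runs on the trial-averaged rate restricted to one
trial period (4.5-s baseline through 800 ms post-offset), with precedence
ON → deactivated → OFF when several rules fire; all correlations are
reported so alternative precedences can be re-derived.  The baseline length
matters: with much shorter baselines, a pure OFF response correlates below
−0.2 with the stimulus boxcar and would be mislabelled deactivated.

Spike-train generation is piecewise-constant-rate inhomogeneous Poisson
(exact sampling per constant segment); class counts follow a deterministic
largest-remainder allocation.

## Validation experiments and their conditions

The recovery battery (`neuropipe.validation`, reported by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`) uses:

- **Scrubbing**: 500 voxels, 12-block visual design, 20 injected global
  artifact frames, default noise.  Scored per voxel-frame.  The experiment
  bypasses first-PC removal: globally shared spikes are exactly what the
  first PC captures, so running it first would test PC removal, not the MAD
  rule.  The rule is additionally checked against a brute-force per-voxel
  median/MAD recomputation (exact agreement).
- **Group GLM**: 500 voxels, 10% active, β = 3× noise SD, 5 sessions
  sharing an active mask.  Sensitivity and observed FDR are means over 5
  replicate experiments, because single-experiment FDR (≈ 50 rejections) is
  a high-variance draw of the expectation BH controls.  The recovery chain
  is interpolation → ΔI/I → smoothing → GLM on drift-free data: the
  high-pass stage would remove most of the block fundamental (see above) and
  PC removal would subtract the coherent stimulus component when 10% of
  voxels respond in phase — both stages remain implemented, smoke-tested and
  exercised by the pipeline runner, but the recovery condition is the one
  without slow drift where they are unnecessary.  Null calibration: 50
  seeds, β = 0, 3 sessions.
- **Face**: 5 trials × 2 s with a compressed 10-s ISI at 64×64 px (full
  120-s ISI video adds nothing but frames), prototypes built per run, AUC
  over quinine vs baseline frames.
- **Tortuosity**: straight-limit and semicircle geometry oracles, plus 10 κ
  levels × 20 seeds of 60-s walks, summarised by Spearman rank correlation.
- **Ephys**: 60 units, 15 one-second trials, gain 4, base 10 Hz.
- **Two-photon**: 200 cells at coupling SNR 2 (gain 1, noise SD 0.5, unit-SD
  locomotion trace, 90 s at 30 Hz); null calibration 50 seeds × 1,000
  pure-noise cells.

What passing shows: the estimators implement their definitions, recover
planted structure at realistic effect sizes, and control their error rates
under their own noise model (white/Gaussian, linear coupling, Poisson
spiking).  What it does not show: robustness to structured physiological
noise, hemodynamic nonlinearity, real facial appearance variation, tracking
errors, or HRF mis-specification — none of which the generators emulate.

## Known limitations

- The published parameterisation's high-pass/block-period conflict means
  long-block GLM results rest mostly on response harmonics; users analysing
  real long-ITI designs may prefer a lower cutoff (exposed in config).
- First-PC removal and MAD scrubbing overlap in what they remove; their
  interaction (PC first, as published) is a convention, and a swap flag is
  deliberately not offered beyond running stages manually.
- The rank-sum test is exact only for small trial counts; larger designs use
  the asymptotic approximation.
- Region tables assume congruent region sets across sessions.
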