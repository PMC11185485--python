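# neuropipe

A tested, reusable implementation of the multimodal analysis stack used to
validate chronic cranial-window imaging in mice: functional-ultrasound (fUS)
preprocessing and GLM activation mapping, histogram-of-oriented-gradients
(HOG) facial-expression prototype scoring, open-field and head-fixed
behavioural metrics, two-photon locomotion-correlation classification, and
electrophysiological response typing.  Every stage is paired with a
synthetic-data generator with known ground truth, so the whole pipeline can
be exercised and scored end to end without any animal data.

It is written for systems-neuroscience labs that acquire several of these
modalities through one preparation and want the downstream analyses to be
reproducible, parameterised, and tested — rather than a pile of one-off
scripts.

## The analyses

**fUS preprocessing.**  Voxel-wise, in fixed order: linear interpolation to
a constant 2 Hz frame rate; conversion to relative change
ΔI/I = (I − Ī_base)/Ī_base against the mean of the 11 (or 70) frames before
each stimulus onset; a fifth-order zero-phase Butterworth high-pass at
0.056 Hz; removal of the first spatiotemporal principal component
(awake sessions); and motion scrubbing that replaces frames exceeding a
per-voxel threshold

    median(x) + 4.44 · MAD(x),   MAD(x) = median(|x − median(x)|),

by linear interpolation (4.44·MAD ≈ 3σ for Gaussian data).

**fUS activation.**  Stimulus boxcars are convolved with a single-gamma
hemodynamic response function (mode 1.5 s, shape 3), each voxel's smoothed
ΔI/I trace is fit by OLS, and T = β̂/SE(β̂) summarises the session.  Across
sessions, a one-sample t-test on T-scores with Benjamini–Hochberg FDR
correction gives the group map; region-level statistics test the Pearson
correlation of atlas-parcel mean traces with the stimulus timing.

**Facial expressions.**  Unsigned-gradient HOG descriptors (32 px cells,
1 cell per block, 8 orientation bins) per video frame; a *neutral* prototype
averages quiet baseline frames; *pleasure*/*disgust* prototypes average the
10 tastant-period frames least correlated with neutral; per-frame Pearson
correlation with a prototype gives the similarity trace, compared across
trials with a Wilcoxon rank-sum test.

**Behaviour.**  Open-field positions are downsampled ×3 and smoothed over
0.5 s; tortuosity is path length / chord length in a 1.2-s sliding window,
summarised as the median over running samples (threshold: mean 75th-percentile
control speed).  Head-fixed readouts: paw-keypoint locomotion traces,
ROI motion energy, per-trial z-scoring to the 40 s before onset, and a
locomotion trial split at mean z > 2.

**Two-photon.**  Cells pass a skewness-above-2 QC; the population's first
right singular vector is correlated with locomotion, as is every cell;
BH-corrected p < 0.001 labels cells positive/negative by the sign of r.

**Electrophysiology.**  Spikes are binned at 1 ms and convolved with a
10-ms-SD Gaussian; trial-averaged rates (70-ms smoothing, z-scored to the
4.5 s before onset) are classified by correlation with the stimulus boxcar
(r > 0.2 → ON, r < −0.2 → deactivated) or with the 0–800 ms post-offset
window (r > 0.2 → OFF).

## Worked example

Generate optogenetic-protocol spike trains with known phenotypes and
classify them:

```python
import numpy as np
from neuropipe import synth, ephys

design = synth.gen_stimulus_design("opto_ephys", seed=0)
trains, labels = synth.gen_spike_trains(
    design, n_cells=8, class_mix=(0.4, 0.2, 0.2, 0.2),
    base_rate_hz=10.0, mod_gain=4.0, seed=0)

for train, truth in zip(trains, labels):
    rate = ephys.firing_rate(train)            # 1-ms bins, 10-ms kernel
    avg = ephys.trial_average_z(rate, design)  # 70-ms smooth, z to 4.5 s
    cls, r = ephys.classify_response(avg)      # r > 0.2 rules
    print(f"unit {train.unit_id}: true={truth:12s} predicted={cls:12s} "
          f"r_stim={r['r_stim']:+.2f} r_off={r['r_off']:+.2f}")
```

```
unit 0: true=ON           predicted=ON           r_stim=+0.96 r_off=-0.16
unit 1: true=ON           predicted=ON           r_stim=+0.94 r_off=-0.15
unit 2: true=ON           predicted=ON           r_stim=+0.96 r_off=-0.13
unit 3: true=deactivated  predicted=deactivated  r_stim=-0.67 r_off=+0.07
unit 4: true=deactivated  predicted=deactivated  r_stim=-0.72 r_off=+0.10
unit 5: true=OFF          predicted=OFF          r_stim=-0.17 r_off=+0.93
unit 6: true=OFF          predicted=OFF          r_stim=-0.12 r_off=+0.93
unit 7: true=none         predicted=none         r_stim=-0.13 r_off=-0.14
```

Each line shows a unit's generated phenotype, the class recovered from its
spike train alone, and the two correlations the rules act on: ON cells
correlate strongly with the stimulus window, deactivated cells negatively,
and OFF cells only with the post-offset window.

The same workflow is available from the shell, e.g.:

```bash
neuropipe synth spikes --n-cells 8 --seed 0 --out spikes.csv
neuropipe ephys classify --spikes spikes.csv --design spikes.design.csv --out classes.csv
```

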