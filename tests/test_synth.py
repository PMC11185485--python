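import numpy as np
import pytest

from neuropipe import synth
from neuropipe.design import StimulusDesign
from neuropipe.fus_activation import make_hrf


class TestStimulusDesign:
    def test_visual_block_structure(self, visual_design):
        assert len(visual_design.events) == 12
        onsets = visual_design.onsets
        assert onsets[0] == 12.0
        assert np.allclose(np.diff(onsets), 24.0)
        assert np.all(visual_design.durations == 12.0)
        # 4 cardinal directions, each repeated 3x
        labels = visual_design.conditions
        assert sorted(set(labels)) == ["0", "180", "270", "90"]
        assert all(labels.count(d) == 3 for d in set(labels))

    def test_opto_fus_onsets(self):
        d = synth.gen_stimulus_design("opto_fus", seed=5)
        assert len(d.events) == 15
        assert np.allclose(d.onsets, 90.0 + 100.0 * np.arange(15))
        assert np.all(d.durations == 10.0)
        strict = synth.gen_stimulus_design("opto_fus", strict_period=True)
        assert np.allclose(np.diff(strict.onsets), 90.0)

    def test_opto_ephys_period(self, opto_ephys_design):
        assert np.allclose(np.diff(opto_ephys_design.onsets), 10.0)
        assert np.all(opto_ephys_design.durations == 1.0)

    def test_seeded_determinism(self):
        a = synth.gen_stimulus_design("visual_block", seed=0)
        b = synth.gen_stimulus_design("visual_block", seed=0)
        assert a.events == b.events

    def test_unknown_protocol_names_valid_ones(self):
        with pytest.raises(ValueError, match="visual_block"):
            synth.gen_stimulus_design("nope")

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            StimulusDesign(events=((5.0, 2.0, "a"), (3.0, 1.0, "a")),
                           run_length_s=20.0)
        with pytest.raises(ValueError):
            StimulusDesign(events=((0.0, 5.0, "a"), (3.0, 1.0, "a")),
                           run_length_s=20.0)
        with pytest.raises(ValueError):
            StimulusDesign(events=((0.0, 30.0, "a"),), run_length_s=20.0)


class TestGenFusSeries:
    def test_null_signal_is_constant_baseline(self, visual_design):
        s, truth = synth.gen_fus_series(visual_design, n_voxels=5, beta=0.0,
                                        noise_sd=0.0, seed=0)
        assert np.allclose(s.doppler, s.doppler[:, :1])
        assert truth.active_mask.sum() == 0 or np.all(truth.true_beta[truth.active_mask] == 0)

    def test_artifact_bookkeeping(self, visual_design):
        _, truth = synth.gen_fus_series(visual_design, n_voxels=5,
                                        n_artifacts=5, seed=1)
        assert truth.artifact_frames.size == 5
        assert np.unique(truth.artifact_frames).size == 5

    def test_noiseless_active_voxel_matches_convolution_oracle(self, visual_design):
        """With zero noise an active voxel is exactly the closed-form
        HRF-convolved boxcar, scaled by beta on its baseline."""
        beta = 0.05
        s, truth = synth.gen_fus_series(visual_design, n_voxels=10, beta=beta,
                                        frac_active=0.5, noise_sd=0.0, seed=2)
        # independent oracle: direct convolution of the boxcar with the kernel
        t = s.t
        hrf = make_hrf(2.0)
        box = np.zeros(t.size)
        for onset, dur, _ in visual_design.events:
            box[(t >= onset) & (t < onset + dur)] = 1.0
        conv = np.convolve(box, hrf.kernel)[: t.size]
        conv /= conv.max()
        v = np.flatnonzero(truth.active_mask)[0]
        base = s.doppler[v, 0]  # regressor is 0 at t=0
        rel = s.doppler[v] / base - 1.0
        assert np.max(np.abs(rel - beta * conv)) < 1e-9

    def test_rejections(self, visual_design):
        with pytest.raises(ValueError):
            synth.gen_fus_series(visual_design, n_voxels=0)
        with pytest.raises(ValueError):
            synth.gen_fus_series(visual_design, n_voxels=5, noise_sd=-1)

    def test_seeded_bit_reproducibility(self, visual_design):
        a, _ = synth.gen_fus_series(visual_design, n_voxels=5, seed=7)
        b, _ = synth.gen_fus_series(visual_design, n_voxels=5, seed=7)
        assert np.array_equal(a.doppler, b.doppler)


class TestGenFaceSequence:
    def test_all_neutral_design(self):
        d = StimulusDesign(events=(), run_length_s=3.0)
        stack, truth = synth.gen_face_sequence(d, frame_rate_hz=10.0,
                                               image_size=(64, 64), seed=0)
        assert all(l == "neutral" for l in truth.labels)
        assert np.all(truth.intensity == 0)

    def test_quinine_frame_count(self, short_tastant_design):
        stack, truth = synth.gen_face_sequence(short_tastant_design,
                                               image_size=(64, 64), seed=0)
        assert truth.labels.count("disgust") == 5 * 40
        assert np.all(truth.intensity[[l == "disgust" for l in truth.labels]] > 0)

    def test_seeded_stacks_bit_identical(self):
        d = synth.gen_tastant_design(n_trials=1, isi_s=2.0, baseline_s=2.0)
        a, _ = synth.gen_face_sequence(d, image_size=(64, 64), seed=3)
        b, _ = synth.gen_face_sequence(d, image_size=(64, 64), seed=3)
        assert np.array_equal(a, b)

    def test_small_frames_rejected(self):
        d = StimulusDesign(events=(), run_length_s=1.0)
        with pytest.raises(ValueError):
            synth.gen_face_sequence(d, image_size=(32, 32))


class TestGenTrajectory:
    def test_sample_count(self):
        traj = synth.gen_trajectory(duration_s=600.0, frame_rate_hz=20.0, seed=0)
        assert traj.n == 12_000

    def test_concentration_orders_tortuosity(self):
        from neuropipe import behavior as bh

        meds = []
        for kappa in (2.0, 200.0):
            vals = []
            for s in range(10):
                tj = synth.gen_trajectory(duration_s=60, frame_rate_hz=20,
                                          turn_concentration=kappa, seed=100 + s)
                _, m = bh.tortuosity(bh.preprocess_trajectory(tj))
                vals.append(m)
            meds.append(np.median(vals))
        assert meds[0] > meds[1]

    def test_positions_inside_arena(self):
        tj = synth.gen_trajectory(duration_s=120, arena_cm=40.0,
                                  turn_concentration=5.0, seed=1)
        assert tj.x.min() >= 0 and tj.x.max() <= 40.0
        assert tj.y.min() >= 0 and tj.y.max() <= 40.0


class TestGenCellTraces:
    def test_pure_positive_zero_noise(self):
        loco = synth.gen_locomotion(300, seed=0)
        traces, labels = synth.gen_cell_traces(4, loco, frac_pos=1.0,
                                               frac_neg=0.0, noise_sd=0.0)
        assert all(l == "positive" for l in labels)
        for row in traces:
            assert np.corrcoef(row, loco)[0, 1] == pytest.approx(1.0)

    def test_label_allocation(self):
        loco = synth.gen_locomotion(100, seed=0)
        _, labels = synth.gen_cell_traces(100, loco, frac_pos=0.6, frac_neg=0.2)
        assert labels.count("positive") == 60
        assert labels.count("negative") == 20

    def test_short_locomotion_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_cell_traces(5, np.zeros(5))


class TestGenSpikeTrains:
    def test_deterministic_allocation(self, opto_ephys_design):
        _, labels = synth.gen_spike_trains(opto_ephys_design, n_cells=20,
                                           class_mix=(0.5, 0.1, 0.2, 0.2))
        assert [labels.count(c) for c in synth.SPIKE_CLASSES] == [10, 2, 4, 4]

    def test_none_cells_poisson_mean(self, opto_ephys_design):
        """Spike count of a constant-rate cell matches base_rate x T within
        3 SE of the mean across 100 seeds (Poisson counting oracle)."""
        T = opto_ephys_design.run_length_s
        base = 10.0
        counts = []
        for s in range(100):
            trains, _ = synth.gen_spike_trains(
                opto_ephys_design, n_cells=1, class_mix=(0, 0, 0, 1.0),
                base_rate_hz=base, mod_gain=4.0, seed=s)
            counts.append(trains[0].times.size)
        se = np.sqrt(base * T / 100)
        assert abs(np.mean(counts) - base * T) < 3 * se

    def test_on_cell_in_stimulus_rate(self, opto_ephys_design):
        base, gain = 10.0, 8.0
        trains, _ = synth.gen_spike_trains(opto_ephys_design, n_cells=1,
                                           class_mix=(1.0, 0, 0, 0),
                                           base_rate_hz=base, mod_gain=gain,
                                           seed=0)
        t = trains[0].times
        in_stim = sum(((t >= o) & (t < o + d)).sum()
                      for o, d, _ in opto_ephys_design.events)
        dur_total = opto_ephys_design.durations.sum()
        expect = base * gain * dur_total
        assert abs(in_stim - expect) < 3 * np.sqrt(expect)

    def test_gain_at_most_one_rejected(self, opto_ephys_design):
        with pytest.raises(ValueError):
            synth.gen_spike_trains(opto_ephys_design, mod_gain=1.0)

    def test_seeded_reproducibility(self, opto_ephys_design):
        a, _ = synth.gen_spike_trains(opto_ephys_design, n_cells=3, seed=4)
        b, _ = synth.gen_spike_trains(opto_ephys_design, n_cells=3, seed=4)
        for x, y in zip(a, b):
            assert np.array_equal(x.times, y.times)
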