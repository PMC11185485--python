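import numpy as np
import pytest
from scipy import stats

from neuropipe import fus_activation as fa
from neuropipe import fus_preprocess as fp
from neuropipe.design import StimulusDesign

from conftest import hand_bh, hand_pearson


def series_of(doppler, fr=2.0, stage="dII"):
    doppler = np.atleast_2d(np.asarray(doppler, float))
    t = np.arange(doppler.shape[1]) / fr
    return fp.FusSeries(doppler=doppler, t=t, frame_rate_hz=fr, stage=stage)


class TestMakeHrf:
    def test_unit_peak_and_nonnegative(self):
        hrf = fa.make_hrf(2.0)
        assert hrf.kernel.max() == pytest.approx(1.0)
        assert np.all(hrf.kernel >= 0)

    def test_mode_at_peak_time(self):
        # gamma mode = (shape - 1) * scale = peak_time by construction
        hrf = fa.make_hrf(2.0, peak_time_s=1.5, shape=3.0)
        assert hrf.kernel.argmax() == int(round(1.5 * 2.0))

    def test_unresolvable_kernel_rejected(self):
        with pytest.raises(ValueError):
            fa.make_hrf(0.5, peak_time_s=1.5)


class TestDesignMatrix:
    def test_empty_design_intercept_only(self):
        d = StimulusDesign(events=(), run_length_s=10.0)
        hrf = fa.make_hrf(2.0)
        X, names = fa.build_design_matrix(d, hrf, np.arange(20) / 2.0)
        assert X.shape == (20, 1)
        assert names == ["intercept"]

    def test_single_frame_event_is_impulse_response(self):
        hrf = fa.make_hrf(2.0)
        d = StimulusDesign(events=((5.0, 0.5, "s"),), run_length_s=30.0)
        t = np.arange(60) / 2.0
        X, _ = fa.build_design_matrix(d, hrf, t)
        reg = X[:, 1]
        onset = 10
        assert np.allclose(reg[onset : onset + hrf.kernel.size], hrf.kernel)
        assert np.allclose(reg[:onset], 0.0)

    def test_block_regressor_period(self):
        """12 s on / 12 s off at 2 Hz gives a 48-sample periodic regressor."""
        events = tuple((12.0 + 24.0 * i, 12.0, "s") for i in range(8))
        d = StimulusDesign(events=events, run_length_s=24.0 * 8)
        hrf = fa.make_hrf(2.0)
        t = np.arange(int(24 * 8 * 2)) / 2.0
        X, _ = fa.build_design_matrix(d, hrf, t)
        reg = X[:, 1]
        interior = reg[48:-48]
        assert np.allclose(interior, reg[96 : 96 + interior.size])

    def test_event_outside_run_rejected(self):
        hrf = fa.make_hrf(2.0)
        d = StimulusDesign(events=((50.0, 5.0, "s"),), run_length_s=60.0)
        with pytest.raises(ValueError):
            fa.build_design_matrix(d, hrf, np.arange(40) / 2.0)


class TestSmoothFrames:
    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=(2, 10))
        out = fa.smooth_frames(series_of(x), n=1)
        assert np.array_equal(out.doppler, x)

    def test_hand_computed_moving_average(self):
        out = fa.smooth_frames(series_of([[0.0, 0, 4, 0, 0]]), n=4)
        # centered window of 4: samples i-1..i+2, shrunk at the edges
        expect = [4 / 3, 1.0, 1.0, 4 / 3, 0.0]
        assert np.allclose(out.doppler[0], expect)

    def test_constant_unchanged(self):
        out = fa.smooth_frames(series_of([[3.0] * 8]), n=4)
        assert np.allclose(out.doppler, 3.0)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            fa.smooth_frames(series_of([[1.0, 2.0]]), n=5)


def ols_oracle(X, y):
    """Hand-coded normal equations: beta, t for column 1."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
    return beta, beta[1] / se


class TestFitGlm:
    def test_exact_noiseless_fit(self):
        rng = np.random.default_rng(1)
        reg = rng.normal(size=30)
        X = np.column_stack([np.ones(30), reg])
        y = 1.0 + 2.0 * reg
        tmap = fa.fit_glm(y[None, :], X)
        assert tmap.beta[0, 0] == pytest.approx(1.0)
        assert tmap.beta[0, 1] == pytest.approx(2.0)
        resid = y - tmap.beta[0] @ X.T
        assert np.max(np.abs(resid)) < 1e-10
        # an exact fit has no noise scale: NaN, or astronomically large t
        assert np.isnan(tmap.tscore[0]) or abs(tmap.tscore[0]) > 1e6

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
            y = rng.normal(size=10)
            tmap = fa.fit_glm(y[None, :], X)
            beta, t = ols_oracle(X, y)
            assert np.allclose(tmap.beta[0], beta, atol=1e-10)
            assert tmap.tscore[0] == pytest.approx(t, abs=1e-10)
            assert tmap.dof == 7

    def test_null_calibration(self):
        """Pure-noise voxels exceed the two-sided 5% t critical value in
        roughly 5% of cases."""
        rng = np.random.default_rng(3)
        n, p = 100, 2
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=(2000, n))
        tmap = fa.fit_glm(y, X)
        crit = stats.t.ppf(0.975, tmap.dof)
        frac = np.mean(np.abs(tmap.tscore) > crit)
        assert 0.03 < frac < 0.07

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError):
            fa.fit_glm(np.zeros((1, 10)), X)


class TestGroupSignificance:
    def make_tmaps(self, T):
        return [fa.TMap(beta=np.zeros((T.shape[1], 2)), tscore=row, dof=10)
                for row in T]

    def test_identical_zero_sessions_nothing_significant(self):
        sig = fa.group_significance(self.make_tmaps(np.zeros((4, 30))))
        assert not sig.significant.any()
        assert np.all(sig.p == 1.0)

    def test_adjusted_p_matches_hand_bh(self):
        rng = np.random.default_rng(4)
        T = rng.normal(size=(5, 50)) + np.linspace(0, 3, 50)
        sig = fa.group_significance(self.make_tmaps(T), alpha=0.05)
        assert np.array_equal(sig.significant, hand_bh(sig.p, 0.05))

    def test_degenerate_nonzero_voxels_flagged(self):
        T = np.zeros((3, 4))
        T[:, 2] = 1.5  # identical nonzero across sessions
        sig = fa.group_significance(self.make_tmaps(T))
        assert 2 in sig.degenerate
        assert sig.p[2] == 0.0

    def test_permutation_null_false_positive_rate(self):
        """Null voxels are declared significant at most alpha of the time
        (mean over replicates, within a binomial margin)."""
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            T = rng.normal(size=(4, 20))
            sig = fa.group_significance(self.make_tmaps(T), alpha=0.05)
            hits += sig.significant.sum()
        rate = hits / (n_rep * 20)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (n_rep * 20))


class TestRegions:
    def test_single_region_identity(self):
        x = np.tile(np.arange(6.0), (4, 1))
        table = fa.segment_regions(series_of(x), np.ones(4, int))
        assert table.traces.shape == (1, 6)
        assert np.allclose(table.traces[0], np.arange(6.0))

    def test_two_voxel_mean(self):
        x = np.array([[0.0] * 5, [2.0] * 5])
        table = fa.segment_regions(series_of(x), np.array([1, 1]))
        assert np.allclose(table.traces[0], 1.0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 8))
        labels = rng.integers(1, 5, size=30)
        table = fa.segment_regions(series_of(x), labels)
        weighted = (table.n_voxels[:, None] * table.traces).sum(axis=0)
        assert np.allclose(weighted, x.sum(axis=0))

    def test_background_excluded(self):
        x = np.ones((3, 4))
        table = fa.segment_regions(series_of(x), np.array([0, 0, 1]))
        assert list(table.region_ids) == [1]
        assert table.n_voxels[0] == 1


class TestRegionActivation:
    def design(self):
        return StimulusDesign(events=((2.0, 2.0, "s"),), run_length_s=8.0)

    def table_from(self, trace):
        trace = np.asarray(trace, float)
        return fa.RegionTable(region_ids=np.array([1]),
                              n_voxels=np.array([1]),
                              traces=trace[None, :],
                              t=np.arange(trace.size) / 2.0)

    def test_boxcar_region_r_one(self):
        d = self.design()
        box = d.boxcar(np.arange(16) / 2.0)
        tables = [self.table_from(box), self.table_from(box)]
        out = fa.region_activation(tables, d)
        assert out.r_mean.iloc[0] == pytest.approx(1.0)

    def test_orthogonal_region_r_zero(self):
        d = self.design()
        t = np.arange(16) / 2.0
        box = d.boxcar(t)
        # sign-balanced within both on and off periods -> exactly r = 0
        trace = np.resize([1.0, -1.0], 16)
        tables = [self.table_from(trace), self.table_from(trace)]
        out = fa.region_activation(tables, d)
        assert abs(out.r_mean.iloc[0]) < 1e-12
        assert abs(hand_pearson(trace, box)) < 1e-12

    def test_matches_hand_pearson(self):
        d = self.design()
        trace = np.array([0.1, 0.3, 0.2, 0.9, 1.1, 0.2, 0.0, 0.1])
        box = d.boxcar(np.arange(8) / 2.0)
        tables = [self.table_from(trace), self.table_from(trace)]
        out = fa.region_activation(tables, d)
        assert out.r_mean.iloc[0] == pytest.approx(hand_pearson(trace, box))


class TestActivityMask:
    def test_all_low_masked(self):
        masked = fa.activity_mask(series_of([[0.01] * 5]))
        assert masked.mask.all()

    def test_high_baseline_voxel_fully_masked(self):
        x = np.vstack([np.full(5, 0.06), np.full(5, 0.03)])
        masked = fa.activity_mask(series_of(x))
        assert masked.mask[0].all()
        assert not masked.mask[1].any()

    def test_boundary_value_kept(self):
        masked = fa.activity_mask(series_of([[0.0175] * 5]))
        assert not masked.mask.any()
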