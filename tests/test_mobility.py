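import numpy as np
import pytest

from mcpalm.correlate import BOUND, UNBOUND
from mcpalm.mobility import (
    MsdCurve,
    distribution_overlap,
    export_displacements,
    fit_diffusion,
    fit_logd_mixture,
    fit_trace,
    pool_msd,
    relative_mobility,
    tamsd,
)
from mcpalm.tracking import ClusterTrack, Trace, interpolate_track

from conftest import make_locs


def brute_force_tamsd(xy, frames, frame_rate):
    """Plain-python all-pairs TAMSD oracle."""
    acc = {}
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            k = frames[j] - frames[i]
            r2 = (xy[j][0] - xy[i][0]) ** 2 + (xy[j][1] - xy[i][1]) ** 2
            acc.setdefault(k, []).append(r2)
    lags = sorted(acc)
    return (
        [k / frame_rate for k in lags],
        [sum(acc[k]) / len(acc[k]) for k in lags],
        [len(acc[k]) for k in lags],
    )


class TestTamsd:
    def test_hand_computed_example(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        c = tamsd(xy, np.array([1, 2, 3]), frame_rate=1.0)
        np.testing.assert_allclose(c.lags_s, [1.0, 2.0])
        np.testing.assert_allclose(c.msd_um2, [1.0, 4.0])
        np.testing.assert_allclose(c.counts, [2, 1])

    def test_immobile_trace_all_zero(self):
        xy = np.zeros((6, 2))
        c = tamsd(xy, np.arange(6), frame_rate=20.0)
        np.testing.assert_allclose(c.msd_um2, 0.0)

    def test_nonuniform_frames_bin_by_true_lag(self):
        # a trace crossing the shutter-cycle boundary has a 3-frame gap
        xy = np.array([[0.0, 0.0], [0.1, 0.0], [0.2, 0.0], [0.3, 0.0]])
        c = tamsd(xy, np.array([8, 9, 10, 13]), frame_rate=20.0)
        assert pytest.approx(c.lags_s.tolist()) == [1 / 20, 2 / 20, 3 / 20, 4 / 20, 5 / 20]

    def test_single_localization_rejected(self):
        with pytest.raises(ValueError):
            tamsd(np.zeros((1, 2)), np.array([1]), 20.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        frames = np.cumsum(rng.integers(1, 4, size=n))
        xy = rng.normal(size=(n, 2))
        c = tamsd(xy, frames, frame_rate=20.0)
        lags, msd, counts = brute_force_tamsd(xy.tolist(), frames.tolist(), 20.0)
        np.testing.assert_allclose(c.lags_s, lags)
        np.testing.assert_allclose(c.msd_um2, msd)
        np.testing.assert_allclose(c.counts, counts)


class TestFitDiffusion:
    def test_exact_line_inverts_model(self):
        lags = np.arange(1, 6) / 20.0
        msd = 4 * 0.05 * lags + 2 * 0.02**2
        fit = fit_diffusion(MsdCurve(lags_s=lags, msd_um2=msd, counts=np.ones(5)))
        assert fit.D_um2_s == pytest.approx(0.05)
        assert fit.sigma_um == pytest.approx(0.02)

    def test_flat_curve_gives_zero_d(self):
        lags = np.arange(1, 6) / 20.0
        msd = np.full(5, 2 * 0.03**2)
        fit = fit_diffusion(MsdCurve(lags_s=lags, msd_um2=msd, counts=np.ones(5)))
        assert fit.D_um2_s == pytest.approx(0.0, abs=1e-12)
        assert fit.sigma_um == pytest.approx(0.03)

    def test_negative_slope_kept_and_flagged(self):
        lags = np.array([0.05, 0.10])
        msd = np.array([0.02, 0.01])
        fit = fit_diffusion(MsdCurve(lags_s=lags, msd_um2=msd, counts=np.ones(2)))
        assert fit.D_um2_s < 0
        assert not fit.valid

    def test_negative_intercept_reports_nan_sigma(self):
        lags = np.array([0.05, 0.10])
        msd = np.array([0.001, 0.004])
        fit = fit_diffusion(MsdCurve(lags_s=lags, msd_um2=msd, counts=np.ones(2)))
        assert np.isnan(fit.sigma_um)
        assert fit.sigma2_um2 < 0

    def test_long_noiseless_walks_unbiased(self):
        from mcpalm.simulate import simulate_trace_ensemble

        D = 0.05
        traces = simulate_trace_ensemble(150, D, mean_length=200, min_length=150,
                                         noise_nm=0.0, seed=9)
        ds = [fit_trace(t, 20.0, max_lags=3).D_um2_s for t in traces]
        assert np.mean(ds) == pytest.approx(D, rel=0.05)


class TestPoolMsd:
    def test_count_weighted_average(self):
        a = MsdCurve(lags_s=np.array([0.05]), msd_um2=np.array([1.0]), counts=np.array([3]))
        b = MsdCurve(lags_s=np.array([0.05, 0.10]), msd_um2=np.array([2.0, 5.0]),
                     counts=np.array([1, 2]))
        pooled = pool_msd([a, b])
        np.testing.assert_allclose(pooled.lags_s, [0.05, 0.10])
        assert pooled.msd_um2[0] == pytest.approx((1.0 * 3 + 2.0 * 1) / 4)
        assert pooled.msd_um2[1] == pytest.approx(5.0)


class TestMixture:
    def test_single_lognormal_selects_one_component(self):
        rng = np.random.default_rng(10)
        mix = fit_logd_mixture(10 ** rng.normal(-1.0, 0.3, 500), seed=0)
        assert mix.n_components == 1
        assert mix.means_log10[0] == pytest.approx(-1.0, abs=0.05)

    def test_two_mode_sample_prefers_two_components(self):
        rng = np.random.default_rng(11)
        Ds = np.concatenate([10 ** rng.normal(-2.1, 0.25, 400), 10 ** rng.normal(-0.68, 0.25, 400)])
        mix = fit_logd_mixture(Ds, seed=0)
        assert mix.n_components == 2
        assert mix.bic_by_k[1] > mix.bic_by_k[2]
        np.testing.assert_allclose(mix.means_log10, [-2.1, -0.68], atol=0.15)

    def test_non_positive_values_excluded_and_counted(self):
        rng = np.random.default_rng(12)
        Ds = np.concatenate([10 ** rng.normal(-1.0, 0.2, 100), [-0.01, 0.0, np.nan]])
        mix = fit_logd_mixture(Ds, seed=0)
        assert mix.n_excluded == 3
        assert mix.n_used == 100

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_logd_mixture(np.full(50, 0.1))
        with pytest.raises(ValueError):
            fit_logd_mixture(np.array([0.1, 0.2]))


class TestOverlap:
    def test_identical_samples_full_overlap(self):
        rng = np.random.default_rng(13)
        a = 10 ** rng.normal(-1, 0.3, 2000)
        assert distribution_overlap(a, a) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_supports_no_overlap(self):
        rng = np.random.default_rng(14)
        a = 10 ** rng.normal(-6, 0.05, 1000)
        b = 10 ** rng.normal(2, 0.05, 1000)
        assert distribution_overlap(a, b) == pytest.approx(0.0, abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(15)
        a = 10 ** rng.normal(-2, 0.3, 800)
        b = 10 ** rng.normal(-1, 0.4, 900)
        assert distribution_overlap(a, b) == pytest.approx(distribution_overlap(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distribution_overlap([], [0.1])

    def test_bound_vs_unbound_mobility_overlap_large_despite_good_classification(
        self, default_experiment, default_result
    ):
        # the motivating ordering: apparent-D distributions of bound and
        # unbound traces overlap substantially, while the correlative
        # (geometric) classification errs on <5% of traces
        from mcpalm.simulate import ground_truth_compare

        res = default_result
        d = res.diffusion
        bound = d.loc[(d["label"] == BOUND) & d["valid"], "D_um2_s"]
        unbound = d.loc[(d["label"] == UNBOUND) & d["valid"], "D_um2_s"]
        ov = distribution_overlap(bound, unbound)
        sc = ground_truth_compare(res.traces, res.classes, default_experiment.truth, 20.0)
        assert ov > 0.3
        assert 1.0 - sc.accuracy < 0.05
        assert 1.0 - sc.accuracy < ov


class TestRelativeMobility:
    def co_moving_scene(self, extra_d=0.0, seed=16):
        # one true full-rate Brownian path; the cluster track sees it at the
        # conventional frames, riders sample the same path at PALM frames
        rng = np.random.default_rng(seed)
        n_frames = 400
        D = 0.01
        steps = rng.normal(scale=np.sqrt(2 * D * 0.05), size=(n_frames - 1, 2))
        path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        conv = np.arange(0, n_frames, 10)
        track = interpolate_track(
            ClusterTrack(id=0, frames=(conv + 1).astype(np.int64),
                         x=path[conv, 0], y=path[conv, 1],
                         width_nm=np.full(len(conv), 380.0),
                         precision_nm=np.full(len(conv), 30.0))
        )
        traces = []
        for i in range(25):
            f0 = int(rng.integers(0, len(conv) - 2)) * 10 + 3
            fs = np.arange(f0, f0 + 6)
            if extra_d > 0:
                w = np.vstack([[0.0, 0.0],
                               np.cumsum(rng.normal(scale=np.sqrt(2 * extra_d * 0.05),
                                                    size=(len(fs) - 1, 2)), axis=0)])
            else:
                w = np.zeros((len(fs), 2))
            traces.append(Trace(id=i, locs=make_locs(
                [(path[f - 1, 0] + w[k, 0], path[f - 1, 1] + w[k, 1], f)
                 for k, f in enumerate(fs)]
            )))
        return track, traces

    def test_rigid_riders_ratio_near_one(self):
        track, traces = self.co_moving_scene(extra_d=0.0)
        out = relative_mobility(track, traces, frame_rate=20.0)
        assert out["ratio"] == pytest.approx(1.0, abs=0.35)

    def test_local_motion_raises_ratio(self):
        track, rigid = self.co_moving_scene(extra_d=0.0)
        _, mobile = self.co_moving_scene(extra_d=0.05)
        r_rigid = relative_mobility(track, rigid, frame_rate=20.0)["ratio"]
        r_mobile = relative_mobility(track, mobile, frame_rate=20.0)["ratio"]
        assert r_mobile > r_rigid
        assert r_mobile > 1.0

    def test_requires_bound_traces(self):
        track, _ = self.co_moving_scene()
        with pytest.raises(ValueError):
            relative_mobility(track, [], frame_rate=20.0)


class TestExportDisplacements:
    def test_one_row_per_displacement(self, tmp_path):
        traces = [
            Trace(id=0, locs=make_locs([(0.0, 0.0, 3), (0.1, 0.0, 4), (0.2, 0.1, 5)])),
            Trace(id=1, locs=make_locs([(1.0, 1.0, 7), (1.1, 1.0, 8)])),
        ]
        path = tmp_path / "disp.csv"
        df = export_displacements(traces, 20.0, path)
        assert len(df) == 3
        assert path.exists()
        assert df.loc[0, "dt_s"] == pytest.approx(0.05)
        assert df.loc[2, "trace_id"] == 1
        np.testing.assert_allclose(df["r_um"], np.hypot(df["dx_um"], df["dy_um"]))
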