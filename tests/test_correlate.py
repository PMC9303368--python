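import numpy as np
import pandas as pd
import pytest

from mcpalm.correlate import (
    BOUND,
    PARTIALLY_BOUND,
    UNBOUND,
    classify_traces,
    colocalize,
    motion_correct,
)
from mcpalm.tracking import ClusterTrack, Trace, interpolate_track

from conftest import make_locs


def track_at(track_id, x, y, radius_nm=376.0, precision_nm=30.0, frames=(1, 101)):
    n = 2
    t = ClusterTrack(
        id=track_id,
        frames=np.array(frames, dtype=np.int64),
        x=np.full(n, float(x)),
        y=np.full(n, float(y)),
        width_nm=np.full(n, radius_nm),
        precision_nm=np.full(n, precision_nm),
    )
    return interpolate_track(t)


def registered(df, precision_nm=20.0):
    out = df.copy()
    out["precision"] = precision_nm
    out.attrs["channel"] = "conventional"
    return out


class TestColocalize:
    def test_localization_at_center_is_colocalized(self):
        sm = registered(make_locs([(0.0, 0.0, 5)]))
        out = colocalize(sm, [track_at(0, 0.0, 0.0)])
        assert out.loc[0, "cluster_id"] == 0

    def test_distance_rule_radius_plus_both_precisions(self):
        # threshold = 376 + 30 + 20 nm = 426 nm; point at 500 nm stays outside
        sm = registered(make_locs([(0.500, 0.0, 5)]), precision_nm=20.0)
        out = colocalize(sm, [track_at(0, 0.0, 0.0, radius_nm=376.0, precision_nm=30.0)])
        assert out.loc[0, "cluster_id"] == -1
        # at 400 nm the same rule accepts it
        sm2 = registered(make_locs([(0.400, 0.0, 5)]), precision_nm=20.0)
        assert colocalize(sm2, [track_at(0, 0.0, 0.0)]).loc[0, "cluster_id"] == 0

    def test_nearest_track_wins_and_ties_take_lower_id(self):
        tracks = [track_at(0, 0.0, 0.0), track_at(1, 0.5, 0.0)]
        sm = registered(make_locs([(0.2, 0.0, 5)]))
        assert colocalize(sm, tracks).loc[0, "cluster_id"] == 0
        sm_mid = registered(make_locs([(0.25, 0.0, 5)]))
        assert colocalize(sm_mid, tracks).loc[0, "cluster_id"] == 0  # exact tie -> lower id

    def test_track_undefined_outside_observation_window(self):
        sm = registered(make_locs([(0.0, 0.0, 150)]))
        out = colocalize(sm, [track_at(0, 0.0, 0.0, frames=(1, 101))])
        assert out.loc[0, "cluster_id"] == -1

    def test_unregistered_input_rejected(self):
        sm = make_locs([(0.0, 0.0, 5)])
        sm["precision"] = 20.0
        with pytest.raises(ValueError, match="registered"):
            colocalize(sm, [track_at(0, 0.0, 0.0)])


def trace_from(xys_frames, trace_id=0):
    return Trace(id=trace_id, locs=make_locs(xys_frames))


def assignments_for(sm, tracks):
    return colocalize(registered(sm), tracks)


class TestClassifyTraces:
    def make_scene(self):
        return [track_at(0, 0.0, 0.0), track_at(7, 5.0, 5.0)]

    def test_all_inside_is_bound_with_host(self):
        tracks = self.make_scene()
        tr = trace_from([(5.0, 5.0, f) for f in range(3, 8)])
        cls = classify_traces([tr], assignments_for(tr.locs, tracks), tracks)
        assert cls.loc[0, "label"] == BOUND
        assert cls.loc[0, "cluster_id"] == 7

    def test_none_inside_is_unbound(self):
        tracks = self.make_scene()
        tr = trace_from([(2.5, 2.5, f) for f in range(3, 9)])
        cls = classify_traces([tr], assignments_for(tr.locs, tracks), tracks)
        assert cls.loc[0, "label"] == UNBOUND

    def test_some_inside_is_partially_bound(self):
        tracks = self.make_scene()
        rows = [(0.0, 0.0, 3), (0.0, 0.0, 4), (2.0, 0.0, 5), (2.0, 0.0, 6), (2.0, 0.0, 7)]
        cls = classify_traces([trace_from(rows)], assignments_for(make_locs(rows), tracks), tracks)
        assert cls.loc[0, "label"] == PARTIALLY_BOUND

    def test_trace_touching_two_clusters_flagged(self):
        tracks = self.make_scene()
        rows = [(0.0, 0.0, 3), (0.0, 0.0, 4), (5.0, 5.0, 5), (5.0, 5.0, 6)]
        cls = classify_traces([trace_from(rows)], assignments_for(make_locs(rows), tracks), tracks)
        assert cls.loc[0, "label"] == PARTIALLY_BOUND
        assert bool(cls.loc[0, "multi_cluster"])

    def test_bound_when_outside_frames_fall_beyond_cluster_window(self):
        track = track_at(0, 0.0, 0.0, frames=(1, 9))
        rows = [(0.0, 0.0, f) for f in (5, 6, 7, 8, 9)] + [(0.0, 0.3, 10), (0.0, 0.6, 11)]
        # frames 10-11 are after the cluster's last conventional frame: the
        # molecule did not leave, the cluster observation ended
        cls = classify_traces([trace_from(rows)], assignments_for(make_locs(rows), [track]), [track])
        assert cls.loc[0, "label"] == BOUND
        assert not bool(cls.loc[0, "excluded_short"])

    def test_bound_on_too_few_defined_frames_flagged_excluded(self):
        track = track_at(0, 0.0, 0.0, frames=(1, 6))
        rows = [(0.0, 0.0, 5), (0.0, 0.0, 6), (0.3, 0.0, 7), (0.6, 0.0, 8), (0.9, 0.0, 9)]
        cls = classify_traces([trace_from(rows)], assignments_for(make_locs(rows), [track]), [track])
        assert cls.loc[0, "label"] == BOUND
        assert bool(cls.loc[0, "excluded_short"])

    def test_partition_is_exhaustive_and_translation_invariant(self):
        tracks = self.make_scene()
        traces = [
            trace_from([(0.0, 0.0, f) for f in range(3, 8)], 0),
            trace_from([(2.5, 2.5, f) for f in range(3, 8)], 1),
            trace_from([(0.0, 0.0, 3), (0.0, 0.0, 4), (2.0, 0.0, 5), (2.0, 0.0, 6)], 2),
        ]
        sm = pd.concat([t.locs for t in traces])
        sm.index = range(len(sm))
        off = 0
        for t in traces:
            t.locs.index = range(off, off + len(t.locs))
            off += len(t.locs)
        cls = classify_traces(traces, assignments_for(sm, tracks), tracks)
        assert sorted(cls["label"]) == sorted([BOUND, UNBOUND, PARTIALLY_BOUND])
        # translate everything by (3, -2): same labels
        dx, dy = 3.0, -2.0
        sm2 = sm.copy()
        sm2["x"] += dx
        sm2["y"] += dy
        tracks2 = [track_at(0, dx, dy), track_at(7, 5.0 + dx, 5.0 + dy)]
        traces2 = []
        for t in traces:
            l2 = t.locs.copy()
            l2["x"] += dx
            l2["y"] += dy
            traces2.append(Trace(id=t.id, locs=l2))
        cls2 = classify_traces(traces2, assignments_for(sm2, tracks2), tracks2)
        assert cls2["label"].tolist() == cls["label"].tolist()


class TestMotionCorrect:
    def moving_track(self, n_conv=11, step=0.5):
        frames = np.arange(n_conv, dtype=np.int64) * 10 + 1
        x = np.arange(n_conv) * step
        t = ClusterTrack(id=3, frames=frames, x=x, y=np.zeros(n_conv),
                         width_nm=np.full(n_conv, 380.0), precision_nm=np.full(n_conv, 30.0))
        return interpolate_track(t)

    def test_rigid_riders_reduce_to_fixed_offsets(self):
        track = self.moving_track()
        frames = [13, 14, 15, 16, 17, 18]
        riders = []
        for i, off in enumerate((0.1, -0.1)):
            xs = [(track.center_at([f])[0][0] + off, 0.0, f) for f in frames]
            riders.append(Trace(id=i, locs=make_locs(xs)))
        cc = motion_correct(track, riders)
        for off, tid in ((0.1, 0), (-0.1, 1)):
            got = cc.locs.loc[cc.locs["trace_id"] == tid, "dx"]
            np.testing.assert_allclose(got, off, atol=1e-12)
        np.testing.assert_allclose(cc.locs["dy"], 0.0, atol=1e-12)

    def test_within_frame_geometry_preserved(self):
        rng = np.random.default_rng(2)
        track = self.moving_track()
        pts = rng.normal(scale=0.1, size=(4, 2))
        frame = 25
        cx, cy = track.center_at([frame])
        traces = [
            Trace(id=i, locs=make_locs([(cx[0] + p[0], cy[0] + p[1], frame)]))
            for i, p in enumerate(pts)
        ]
        cc = motion_correct(track, traces)
        got = cc.locs[["dx", "dy"]].to_numpy()
        raw = np.array([[t.locs["x"].iloc[0], t.locs["y"].iloc[0]] for t in traces])
        for i in range(4):
            for j in range(4):
                assert np.hypot(*(got[i] - got[j])) == pytest.approx(np.hypot(*(raw[i] - raw[j])))

    def test_stationary_cluster_subtracts_constant(self):
        frames = np.arange(5, dtype=np.int64) * 10 + 1
        t = interpolate_track(ClusterTrack(id=0, frames=frames, x=np.full(5, 2.0),
                                           y=np.full(5, 1.0), width_nm=np.full(5, 380.0),
                                           precision_nm=np.full(5, 30.0)))
        tr = Trace(id=0, locs=make_locs([(2.3, 1.1, 15), (2.2, 0.9, 16)]))
        cc = motion_correct(t, [tr])
        np.testing.assert_allclose(cc.locs["dx"], [0.3, 0.2])
        np.testing.assert_allclose(cc.locs["dy"], [0.1, -0.1])

    def test_localizations_outside_window_excluded_and_counted(self):
        track = self.moving_track(n_conv=2)  # defined for frames 1..11
        tr = Trace(id=0, locs=make_locs([(0.0, 0.0, 9), (0.0, 0.0, 10), (0.0, 0.0, 13)]))
        cc = motion_correct(track, [tr])
        assert cc.n_localizations == 2
        assert cc.n_excluded == 1

    def test_rate_is_count_over_duration(self):
        track = self.moving_track()  # spans frames 1..101 -> 5 s at 20 Hz
        tr = Trace(id=0, locs=make_locs([(0.0, 0.0, f) for f in (13, 14, 15, 16)]))
        cc = motion_correct(track, [tr])
        assert cc.duration_s == pytest.approx(5.0)
        assert cc.localization_rate == pytest.approx(4 / 5.0)

    def test_requires_interpolated_track(self):
        frames = np.arange(5, dtype=np.int64) * 10 + 1
        raw = ClusterTrack(id=0, frames=frames, x=np.zeros(5), y=np.zeros(5),
                           width_nm=np.full(5, 380.0), precision_nm=np.full(5, 30.0))
        with pytest.raises(ValueError, match="interpolated"):
            motion_correct(raw, [])
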